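"""Agreement between self-reported and measured values on the validation subsample.

Bland-Altman limits of agreement, paired t-test, two-way absolute-agreement
single-measure ICC, weighted confusion-matrix summaries with Cohen's kappa and
McNemar's test, and stratification by age band / sex / education.

Survey weights are applied to means, SDs and proportions; McNemar's statistic
uses the unweighted discordant counts, and the ICC is computed on unweighted
pairs.  Undefined ratios (empty margins) propagate as NaN, never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import indicators

Z_LOA = 1.96

AGE_BANDS = [(18, 24), (25, 44), (45, 64), (65, 200)]


@dataclass
class AgreementReport:
    """Bland-Altman style agreement summary for a continuous variable.

    ``mean_diff`` is self-reported minus measured; the limits of agreement are
    mean_diff +/- 1.96 x SD of the differences.
    """

    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    mean_diff_ci: tuple
    loa_lower_ci: tuple
    loa_upper_ci: tuple
    icc: float = math.nan
    icc_ci: tuple = (math.nan, math.nan)
    n_pairs: int = 0
    stratum: str = "all"
    small_stratum: bool = False

    def to_dict(self):
        return asdict(self)


@dataclass
class ConfusionSummary:
    """Weighted 2x2 agreement summary for a binary indicator."""

    tp: float
    fp: float
    fn: float
    tn: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    kappa: float
    mcnemar_stat: float
    mcnemar_p: float
    prevalence_sr: float
    prevalence_meas: float
    n_pairs: int = 0
    stratum: str = "all"
    small_stratum: bool = False

    def to_dict(self):
        return asdict(self)


# ---------------------------------------------------------------------------
# weighted moments

def _check_pairs(a, b, min_n=2):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if len(a) < min_n:
        raise ValueError(f"need at least {min_n} complete pairs, got {len(a)}")
    return a, b, keep


def weighted_mean_sd(x, weights=None):
    """Weighted mean and SD; the SD uses the reliability-weight analogue of
    the n-1 denominator so it reduces to the sample SD for equal weights."""
    x = np.asarray(x, dtype=float)
    if weights is None:
        return float(np.mean(x)), float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    w = np.asarray(weights, dtype=float)
    if np.sum(w) <= 0:
        raise ValueError("total weight must be positive")
    m = float(np.sum(w * x) / np.sum(w))
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    if denom <= 0:
        return m, 0.0
    var = float(np.sum(w * (x - m) ** 2) / denom)
    return m, math.sqrt(max(var, 0.0))


def bland_altman(self_vals, meas_vals, weights=None, stratum="all") -> AgreementReport:
    """Limits of agreement for self-reported minus measured values.

    CI for the mean difference uses the paired-t machinery; CIs for the limits
    use the large-sample SE sd*sqrt(3/n).
    """
    a, b, keep = _check_pairs(self_vals, meas_vals)
    w = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)[keep]
        if np.sum(w) <= 0:
            raise ValueError("total weight must be positive")
    d = a - b
    n = len(d)
    mean_d, sd_d = weighted_mean_sd(d, w)
    tq = stats.t.ppf(0.975, n - 1)
    se_mean = sd_d / math.sqrt(n)
    se_loa = sd_d * math.sqrt(3.0 / n)
    loa_l = mean_d - Z_LOA * sd_d
    loa_u = mean_d + Z_LOA * sd_d
    icc_val, icc_ci = (math.nan, (math.nan, math.nan))
    if n >= 3:
        icc_val, icc_ci = icc_agreement(a, b)
    return AgreementReport(
        mean_diff=mean_d,
        sd_diff=sd_d,
        loa_lower=loa_l,
        loa_upper=loa_u,
        mean_diff_ci=(mean_d - tq * se_mean, mean_d + tq * se_mean),
        loa_lower_ci=(loa_l - tq * se_loa, loa_l + tq * se_loa),
        loa_upper_ci=(loa_u - tq * se_loa, loa_u + tq * se_loa),
        icc=icc_val,
        icc_ci=icc_ci,
        n_pairs=n,
        stratum=stratum,
    )


def paired_mean_difference_test(self_vals, meas_vals):
    """Paired t-test on self minus measured.

    Returns dict with t, p, ci and a ``degenerate`` flag when the differences
    have zero variance (no p-value is reported in that case).
    """
    a, b, _ = _check_pairs(self_vals, meas_vals)
    d = a - b
    n = len(d)
    sd = np.std(d, ddof=1)
    if sd == 0:
        return {
            "t": math.nan, "p": math.nan, "ci": (float(np.mean(d)),) * 2,
            "mean_diff": float(np.mean(d)), "degenerate": True, "n": n,
        }
    t_stat, p = stats.ttest_rel(a, b)
    tq = stats.t.ppf(0.975, n - 1)
    m = float(np.mean(d))
    half = tq * sd / math.sqrt(n)
    return {
        "t": float(t_stat), "p": float(p), "ci": (m - half, m + half),
        "mean_diff": m, "degenerate": False, "n": n,
    }


def icc_agreement(self_vals, meas_vals):
    """Two-way absolute-agreement single-measure ICC (ICC(A,1)) from the
    paired two-way ANOVA mean squares, with the standard F-based 95% CI.

    Absolute agreement (rather than consistency) is the right variant here
    because a systematic self-report shift is exactly what should be
    penalised.
    """
    a, b, _ = _check_pairs(self_vals, meas_vals, min_n=3)
    Y = np.column_stack([a, b])
    n, k = Y.shape
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((Y - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        if sst == 0:  # all values identical: no variance to agree about
            return math.nan, (math.nan, math.nan)
        return 0.0, (math.nan, math.nan)
    icc = (msr - mse) / denom

    # McGraw & Wong CI for ICC(A,1)
    if mse <= 0:
        return float(icc), (float(icc), float(icc))
    alpha = 0.05
    a_c = k * icc / (n * (1 - icc)) if icc < 1 else math.inf
    b_c = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else math.inf
    if not math.isfinite(a_c):
        return float(icc), (float(icc), float(icc))
    v = (a_c * msc + b_c * mse) ** 2 / (
        (a_c * msc) ** 2 / (k - 1) + (b_c * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return float(icc), (float(lower), float(upper))


def cohen_kappa(table: np.ndarray) -> float:
    """Cohen's kappa from a (possibly weighted) k x k agreement table."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    if total <= 0:
        return math.nan
    p = table / total
    po = np.trace(p)
    pe = float(np.sum(p.sum(axis=0) * p.sum(axis=1)))
    if pe == 1.0:
        return math.nan if po == 1.0 else 0.0
    return float((po - pe) / (1.0 - pe))


def confusion(self_flag, meas_flag, weights=None, stratum="all") -> ConfusionSummary:
    """Weighted 2x2 summary treating the measured flag as the reference.

    Sensitivity/specificity/PPV/NPV come from weighted counts; McNemar's
    chi-square (b-c)^2/(b+c) uses the unweighted discordant counts.
    """
    a, b, keep = _check_pairs(self_flag, meas_flag, min_n=1)
    if not set(np.unique(a)) <= {0.0, 1.0} or not set(np.unique(b)) <= {0.0, 1.0}:
        raise ValueError("flags must be binary 0/1")
    w = np.ones(len(a)) if weights is None else np.asarray(weights, float)[keep]
    tp = float(np.sum(w * (a == 1) * (b == 1)))
    fp = float(np.sum(w * (a == 1) * (b == 0)))
    fn = float(np.sum(w * (a == 0) * (b == 1)))
    tn = float(np.sum(w * (a == 0) * (b == 0)))
    tot = tp + fp + fn + tn

    def ratio(num, den):
        return num / den if den > 0 else math.nan

    kappa = cohen_kappa(np.array([[tp, fp], [fn, tn]]))
    b_disc = int(np.sum((a == 1) & (b == 0)))
    c_disc = int(np.sum((a == 0) & (b == 1)))
    if b_disc + c_disc > 0:
        mcnemar_stat = (b_disc - c_disc) ** 2 / (b_disc + c_disc)
        mcnemar_p = float(stats.chi2.sf(mcnemar_stat, 1))
    else:
        mcnemar_stat, mcnemar_p = 0.0, 1.0
    return ConfusionSummary(
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
        kappa=kappa,
        mcnemar_stat=float(mcnemar_stat),
        mcnemar_p=mcnemar_p,
        prevalence_sr=ratio(tp + fp, tot),
        prevalence_meas=ratio(tp + fn, tot),
        n_pairs=len(a),
        stratum=stratum,
    )


# ---------------------------------------------------------------------------
# dataset-level interface

CONTINUOUS_VARIABLES = {"height", "weight", "bmi"}
BINARY_VARIABLES = {"overweight", "obesity", "hypertension", "hypercholesterolemia"}


def _paired_columns(data: pd.DataFrame, variable: str):
    """Self-reported and measured series for one variable on the validation rows."""
    val = data[data["in_validation"] == 1]
    meas_ind = indicators.derive_indicators(
        val["meas_height"], val["meas_weight"],
        sbp=val.get("meas_sbp"), dbp=val.get("meas_dbp"),
        htn_medication=val.get("meas_htn_medication"),
        tchol=val.get("meas_total_cholesterol"),
    )
    sr_bmi = indicators.bmi(val["sr_weight"], val["sr_height"])
    table = {
        "height": (val["sr_height"], val["meas_height"]),
        "weight": (val["sr_weight"], val["meas_weight"]),
        "bmi": (sr_bmi, indicators.bmi(val["meas_weight"], val["meas_height"])),
        "overweight": (indicators.overweight_flag(sr_bmi), meas_ind["overweight"]),
        "obesity": (indicators.obesity_flag(sr_bmi), meas_ind["obesity"]),
        "hypertension": (val["sr_hypertension"], meas_ind.get("hypertension")),
        "hypercholesterolemia": (
            val["sr_hypercholesterolemia"],
            meas_ind.get("hypercholesterolemia"),
        ),
    }
    if variable not in table:
        raise ValueError(f"unknown variable {variable!r}")
    sr, meas = table[variable]
    return (
        np.asarray(sr, dtype=float),
        np.asarray(meas, dtype=float),
        val["weight"].to_numpy(dtype=float),
        val,
    )


def validity_report(data: pd.DataFrame, variable: str, weighted=True):
    """Whole-population agreement report for one variable (validation rows)."""
    sr, meas, w, _ = _paired_columns(data, variable)
    w = w if weighted else None
    if variable in CONTINUOUS_VARIABLES:
        return bland_altman(sr, meas, weights=w)
    return confusion(sr, meas, weights=w)


def stratified_validity(
    data: pd.DataFrame, variable: str, strata: str, weighted=True, min_n=30
):
    """Per-stratum agreement reports plus the whole-population report.

    ``strata`` is one of ``age_band``, ``sex``, ``education``.  Levels with
    fewer than ``min_n`` pairs are flagged, not dropped.
    """
    sr, meas, w, val = _paired_columns(data, variable)
    if strata == "age_band":
        labels = pd.cut(
            val["age"], [b[0] - 0.5 for b in AGE_BANDS] + [AGE_BANDS[-1][1]],
            labels=[f"{lo}-{hi}" for lo, hi in AGE_BANDS],
        ).astype(str)
    elif strata == "sex":
        labels = val["sex"].map({0: "male", 1: "female"}).astype(str)
    elif strata == "education":
        labels = "edu" + val["education"].astype(str)
    else:
        raise ValueError(f"unknown stratum variable {strata!r}")

    reports = [
        bland_altman(sr, meas, weights=w if weighted else None)
        if variable in CONTINUOUS_VARIABLES
        else confusion(sr, meas, weights=w if weighted else None)
    ]
    for level in sorted(labels.unique()):
        mask = (labels == level).to_numpy()
        if mask.sum() < 2:
            continue
        ww = w[mask] if weighted else None
        if variable in CONTINUOUS_VARIABLES:
            rep = bland_altman(sr[mask], meas[mask], weights=ww, stratum=level)
        else:
            rep = confusion(sr[mask], meas[mask], weights=ww, stratum=level)
        rep.small_stratum = bool(mask.sum() < min_n)
        reports.append(rep)
    return reports


def reports_to_frame(reports) -> pd.DataFrame:
    """Long-format table (one row per stratum) for CSV/JSON serialization."""
    return pd.DataFrame([r.to_dict() for r in reports])
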