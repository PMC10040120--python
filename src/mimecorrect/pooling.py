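"""Survey-weighted prevalence estimation and Rubin's-rules pooling.

The prevalence estimator is the weighted ratio mean sum(w*y)/sum(w); its
design-based variance uses Taylor linearization with with-replacement cluster
sampling within strata.  Estimates from the m completed datasets are combined
by Rubin's rules with the Barnard-Rubin small-sample degrees of freedom, and
the fraction of missing information and relative efficiency (1 + gamma/m)^-1
are reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DesignColumns:
    stratum: str = "stratum"
    cluster: str = "cluster"
    weight: str = "weight"


@dataclass
class PooledEstimate:
    qbar: float
    within_var: float
    between_var: float
    total_var: float
    se: float
    df: float
    fmi: float
    relative_efficiency: float
    ci: tuple
    m: int

    def to_dict(self):
        return asdict(self)


def weighted_prevalence(
    data: pd.DataFrame,
    indicator: str,
    design: DesignColumns | None = None,
    single_cluster: str = "collapse",
):
    """Weighted prevalence and its Taylor-linearized design variance.

    ``single_cluster`` controls the policy for strata containing one cluster:
    ``collapse`` merges them into a single pseudo-stratum (with a warning in
    the return value), ``error`` raises.
    Returns ``(estimate, variance)``.
    """
    design = design or DesignColumns()
    y = data[indicator].to_numpy(dtype=float)
    if np.any(np.isnan(y)):
        raise ValueError(f"indicator {indicator!r} contains missing values")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"indicator {indicator!r} must be binary")
    w = data[design.weight].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    wsum = float(np.sum(w))
    est = float(np.sum(w * y) / wsum)

    strata = data[design.stratum].to_numpy()
    clusters = data[design.cluster].to_numpy()
    # linearized score for the ratio estimator
    z = w * (y - est) / wsum

    frame = pd.DataFrame({"s": strata, "c": clusters, "z": z})
    cl = frame.groupby(["s", "c"], sort=False)["z"].sum().reset_index()
    n_per_stratum = cl.groupby("s")["c"].transform("size")
    if (n_per_stratum == 1).any():
        if single_cluster == "error":
            raise ValueError("stratum with a single cluster")
        cl["s"] = cl["s"].astype(object)
        lone = cl["s"].isin(cl.loc[n_per_stratum == 1, "s"])
        cl.loc[lone, "s"] = "__collapsed__"

    var = 0.0
    for _, g in cl.groupby("s"):
        nh = len(g)
        if nh < 2:
            continue  # a single collapsed cluster contributes no variance
        t = g["z"].to_numpy()
        var += nh / (nh - 1) * float(np.sum((t - t.mean()) ** 2))
    return est, var


def design_degrees_of_freedom(data: pd.DataFrame, design: DesignColumns | None = None) -> int:
    """Complete-data degrees of freedom: clusters minus strata."""
    design = design or DesignColumns()
    pairs = data[[design.stratum, design.cluster]].drop_duplicates()
    n_clusters = len(pairs)
    n_strata = pairs[design.stratum].nunique()
    return max(n_clusters - n_strata, 1)


def rubin_pool(estimates, variances, m=None, complete_df=None) -> PooledEstimate:
    """Combine m completed-data estimates by Rubin's rules.

    Qbar = mean estimate; W = mean within variance; B = between variance
    (sample variance of estimates); T = W + (1 + 1/m) B.  gamma (FMI) =
    (1 + 1/m) B / T; relative efficiency = (1 + gamma/m)^-1.  Degrees of
    freedom follow Barnard-Rubin when ``complete_df`` is given, otherwise the
    classic (m - 1)(1 + W / ((1 + 1/m)B))^2.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if m is None:
        m = len(q)
    if m < 2 or len(q) != len(u):
        raise ValueError("need m >= 2 paired estimates and variances")
    if np.any(u < 0):
        raise ValueError("variances must be >= 0")
    qbar = float(np.mean(q))
    W = float(np.mean(u))
    B = float(np.var(q, ddof=1))
    T = W + (1.0 + 1.0 / m) * B
    gamma = 0.0 if T <= 0 else (1.0 + 1.0 / m) * B / T

    if B <= 0:
        df = float(complete_df) if complete_df is not None else math.inf
    else:
        r = (1.0 + 1.0 / m) * B / W if W > 0 else math.inf
        df_old = (m - 1) * (1.0 + 1.0 / r) ** 2 if math.isfinite(r) else m - 1.0
        if complete_df is not None:
            nu_com = float(complete_df)
            df_obs = (nu_com + 1.0) / (nu_com + 3.0) * nu_com * (1.0 - gamma)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
        else:
            df = df_old

    se = math.sqrt(max(T, 0.0))
    tq = stats.t.ppf(0.975, df) if math.isfinite(df) else stats.norm.ppf(0.975)
    return PooledEstimate(
        qbar=qbar,
        within_var=W,
        between_var=B,
        total_var=T,
        se=se,
        df=float(df),
        fmi=gamma,
        relative_efficiency=1.0 / (1.0 + gamma / m),
        ci=(qbar - tq * se, qbar + tq * se),
        m=int(m),
    )


def analyze_completed(
    completed,
    indicators_,
    design: DesignColumns | None = None,
) -> pd.DataFrame:
    """Weighted prevalence per completed copy, pooled by Rubin's rules.

    ``completed`` is a CompletedSet or a list of DataFrames; ``indicators_``
    maps output names to indicator column names present in every copy.
    Returns one row per indicator with the PooledEstimate fields.
    """
    datasets = getattr(completed, "datasets", completed)
    if len(datasets) < 2:
        raise ValueError("need at least 2 completed datasets")
    design = design or DesignColumns()
    cdf = design_degrees_of_freedom(datasets[0], design)
    rows = []
    for name, col in indicators_.items():
        ests, variances = [], []
        for d in datasets:
            if col not in d.columns:
                raise ValueError(f"indicator column {col!r} absent from a completed copy")
            e, v = weighted_prevalence(d, col, design)
            ests.append(e)
            variances.append(v)
        pooled = rubin_pool(ests, variances, complete_df=cdf)
        row = {"indicator": name}
        row.update(pooled.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SERatioReport:
    indicator: str
    se_validation_only: float
    se_adjusted: float
    ratio: float

    def to_dict(self):
        return asdict(self)


def se_ratio(indicator: str, se_validation_only: float, se_adjusted: float) -> SERatioReport:
    """Ratio of the validation-subsample-only design SE to the adjusted
    full-sample SE; > 1 means the correction gained precision over using the
    examination data alone."""
    if se_validation_only <= 0:
        raise ValueError("validation-only SE must be > 0")
    ratio = se_validation_only / se_adjusted if se_adjusted > 0 else math.nan
    return SERatioReport(indicator, se_validation_only, se_adjusted, ratio)


def calibrated_prevalence(
    data: pd.DataFrame,
    model,
    design: DesignColumns | None = None,
):
    """Weighted mean of calibrated predictions with a delta-method SE.

    Variance = design-based Taylor variance of the weighted mean of the
    predictions + g' V g, where g is the gradient of the weighted mean with
    respect to the calibration coefficients and V their covariance.  The
    second term is what blows up when the calibration model is weak.
    """
    from . import calibration as cal

    design = design or DesignColumns()
    pred = cal.predict(model, data)
    w = data[design.weight].to_numpy(dtype=float)
    wsum = float(np.sum(w))
    est = float(np.sum(w * pred) / wsum)

    # design part: linearize around the predictions as if they were responses
    z = w * (pred - est) / wsum
    frame = pd.DataFrame(
        {"s": data[design.stratum].to_numpy(), "c": data[design.cluster].to_numpy(), "z": z}
    )
    cl = frame.groupby(["s", "c"], sort=False)["z"].sum().reset_index()
    var_design = 0.0
    for _, g in cl.groupby("s"):
        nh = len(g)
        if nh < 2:
            continue
        t = g["z"].to_numpy()
        var_design += nh / (nh - 1) * float(np.sum((t - t.mean()) ** 2))

    grad_rows = cal.prediction_gradient(model, data)
    g_mean = (w[:, None] * grad_rows).sum(axis=0) / wsum
    var_coef = float(g_mean @ model.cov_params @ g_mean)
    return est, var_design + max(var_coef, 0.0)
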