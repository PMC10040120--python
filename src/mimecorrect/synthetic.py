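"""Synthetic health-interview-survey generator with a measured validation subsample.

Emulates the structure of a national health interview survey in which a random
subsample of respondents additionally receives a physical examination: every
respondent carries error-prone self-reports of height, weight, hypertension and
hypercholesterolemia, while objective measurements (height, weight, blood
pressure, medication use, total cholesterol) exist only for the validation
subsample. True values are retained in ``true_*`` columns so that downstream
correction methods can be scored against a known truth.

The self-report error model is linear-in-truth with additive Gaussian noise for
continuous variables — an attenuated ("flat") slope so that low values are
over-reported and high values under-reported — with subgroup-specific additive
bias entering through the intercept, and sensitivity/specificity
misclassification for binary conditions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import indicators

EDUCATION_LEVELS = [1, 2, 3, 4]  # no diploma/primary, lower sec., higher sec., higher
TRUTH_COLUMNS = [
    "true_height",
    "true_weight",
    "true_bmi",
    "true_overweight",
    "true_obesity",
    "true_hypertension",
    "true_hypercholesterolemia",
]
MEASURED_COLUMNS = [
    "meas_height",
    "meas_weight",
    "meas_sbp",
    "meas_dbp",
    "meas_htn_medication",
    "meas_total_cholesterol",
]


@dataclass
class TruthParams:
    """Population model for the error-free ("true") values.

    Heights are sex-specific normals with a mild shrinkage above age 45; the
    true BMI is a right-skewed gamma (so obesity sits in the upper tail) and
    weight is derived as BMI x height^2, which fixes the joint height/weight
    distribution.  Binary conditions have age-increasing prevalence centred on
    the stated overall value.
    """

    n_respondents: int = 9439
    height_mean_male: float = 176.5  # cm
    height_mean_female: float = 163.5
    height_sd: float = 6.8
    bmi_offset: float = 18.0  # kg/m^2 floor of the gamma BMI model
    bmi_shape: float = 1.9
    bmi_scale: float = 4.4
    prevalence_hypertension: float = 0.33
    prevalence_hypercholesterolemia: float = 0.47
    age_min: int = 18
    age_max: int = 90
    p_female: float = 0.51
    education_probs: tuple = (0.08, 0.22, 0.35, 0.35)
    n_provinces: int = 11
    wave_year: int = 2018

    def validate(self):
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be >= 1")
        for name in ("prevalence_hypertension", "prevalence_hypercholesterolemia"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.height_sd <= 0 or self.bmi_scale <= 0 or self.bmi_shape <= 0:
            raise ValueError("scale parameters must be > 0")
        if abs(sum(self.education_probs) - 1.0) > 1e-9:
            raise ValueError("education_probs must sum to 1")


@dataclass
class ErrorParams:
    """Self-report error mechanism.

    Continuous:  sr = true + bias(subgroup) + (slope - 1) * (true - mean_true) + eps,
    i.e. intercept-level bias by sex/age/education plus a global attenuation
    slope in (0, 1].  Binary: Bernoulli(sensitivity) for true cases and
    Bernoulli(1 - specificity) for true non-cases.

    Defaults emulate observed national-survey reporting behaviour: mean height
    over-reported by about +1.05 cm (more for women, the elderly, lower
    education), weight under-reported by about -1.50 kg (more for women and the
    highly educated), hypertension reported with sensitivity 0.45 /
    specificity 0.99 and hypercholesterolemia with 0.22 / 0.83.
    """

    height_bias: float = 0.25  # cm, base intercept shift
    height_bias_female: float = 0.70
    height_bias_age65: float = 1.20
    height_bias_low_edu: float = 0.30
    weight_bias: float = -1.00  # kg
    weight_bias_female: float = -0.50
    weight_bias_age65: float = -0.30
    weight_bias_high_edu: float = -0.40
    slope_attenuation: float = 0.85  # global flat-slope factor, in (0, 1]
    height_noise_sd: float = 2.6  # cm
    weight_noise_sd: float = 3.5  # kg
    sens_hypertension: float = 0.45
    spec_hypertension: float = 0.99
    sens_hypercholesterolemia: float = 0.22
    spec_hypercholesterolemia: float = 0.83

    def validate(self):
        for name in (
            "sens_hypertension",
            "spec_hypertension",
            "sens_hypercholesterolemia",
            "spec_hypercholesterolemia",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.slope_attenuation <= 1.0:
            raise ValueError("slope_attenuation must lie in (0, 1]")
        if self.height_noise_sd < 0 or self.weight_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass
class DesignParams:
    """Stratified, clustered, weighted sampling design.

    ``weight_model`` maps a respondent row to a strictly positive design
    weight; the default over-weights the elderly and men, mimicking the
    post-stratification corrections of an interview survey.
    """

    n_strata: int = 11
    clusters_per_stratum: int = 20
    validation_fraction: float = 1184.0 / 9439.0
    weight_model: object = None  # callable DataFrame -> array of weights

    def validate(self):
        if self.n_strata < 1 or self.clusters_per_stratum < 1:
            raise ValueError("n_strata and clusters_per_stratum must be >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0, 1)")


def default_weight_model(df: pd.DataFrame) -> np.ndarray:
    w = np.ones(len(df))
    w += 0.45 * (df["age"].to_numpy() >= 65)
    w += 0.25 * (df["sex"].to_numpy() == 0)  # men under-respond
    w += 0.10 * (df["education"].to_numpy() <= 2)
    return w


def generate_truth(params: TruthParams, seed: int) -> pd.DataFrame:
    """Draw the error-free population: covariates, true anthropometry, true
    blood pressure / cholesterol continuous values consistent with the binary
    condition flags, so threshold logic is exercised end to end."""
    params.validate()
    rng = np.random.default_rng(seed)
    n = params.n_respondents

    sex = (rng.random(n) < params.p_female).astype(int)  # 1 = female
    age = rng.integers(params.age_min, params.age_max + 1, size=n)
    education = rng.choice(EDUCATION_LEVELS, size=n, p=params.education_probs)
    province = rng.integers(0, params.n_provinces, size=n)
    household_size = np.minimum(1 + rng.poisson(1.3, size=n), 8)

    height_mean = np.where(
        sex == 1, params.height_mean_female, params.height_mean_male
    ) - 0.05 * np.maximum(age - 45, 0)
    true_height = rng.normal(height_mean, params.height_sd)
    true_height = np.clip(true_height, 130.0, 215.0)

    true_bmi = params.bmi_offset + rng.gamma(
        params.bmi_shape, params.bmi_scale, size=n
    ) + 0.015 * (age - 54)
    true_bmi = np.clip(true_bmi, 14.0, 60.0)
    true_weight = true_bmi * (true_height / 100.0) ** 2

    p_htn = _age_tilted_prob(params.prevalence_hypertension, age)
    true_htn = (rng.random(n) < p_htn).astype(int)
    p_chol = _age_tilted_prob(params.prevalence_hypercholesterolemia, age)
    true_chol = (rng.random(n) < p_chol).astype(int)

    sbp, dbp, med = _blood_pressure_given_flag(true_htn, rng)
    tchol = _cholesterol_given_flag(true_chol, rng)

    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "age": age,
            "sex": sex,
            "education": education,
            "province": province,
            "household_size": household_size,
            "wave_year": params.wave_year,
            "true_height": true_height,
            "true_weight": true_weight,
            "true_sbp": sbp,
            "true_dbp": dbp,
            "true_htn_medication": med,
            "true_total_cholesterol": tchol,
        }
    )
    df["true_bmi"] = indicators.bmi(df["true_weight"], df["true_height"])
    df["true_overweight"] = indicators.overweight_flag(df["true_bmi"])
    df["true_obesity"] = indicators.obesity_flag(df["true_bmi"])
    # flags below coincide with the thresholds applied to the continuous draws
    df["true_hypertension"] = true_htn.astype(float)
    df["true_hypercholesterolemia"] = true_chol.astype(float)
    return df


def _age_tilted_prob(base: float, age: np.ndarray) -> np.ndarray:
    """Prevalence increasing in age, centred so the overall mean stays ~base."""
    if base in (0.0, 1.0):
        return np.full(len(age), base)
    tilt = 0.004 * (age - np.mean(age))
    return np.clip(base + tilt, 0.01, 0.99)


def _blood_pressure_given_flag(flag: np.ndarray, rng) -> tuple:
    """Continuous blood pressure and medication use consistent with the flag.

    Cases are either treated (medication alone satisfies the definition) or
    have elevated pressure; non-cases are untreated with pressure truncated
    below the 140/90 thresholds.
    """
    n = len(flag)
    sbp = np.empty(n)
    dbp = np.empty(n)
    med = np.zeros(n)

    cases = flag == 1
    n_case = int(cases.sum())
    if n_case:
        treated = rng.random(n_case) < 0.5
        sbp_case = np.where(
            treated,
            rng.normal(133.0, 11.0, n_case),
            140.0 + rng.exponential(11.0, n_case),
        )
        dbp_case = rng.normal(84.0, 8.0, n_case)
        med[cases] = treated.astype(float)
        sbp[cases] = sbp_case
        dbp[cases] = dbp_case
    non = ~cases
    n_non = int(non.sum())
    if n_non:
        # truncated normals keep non-cases strictly inside the normotensive box
        sbp[non] = stats.truncnorm.rvs(
            (95 - 122) / 10.0, (139.9 - 122) / 10.0, loc=122, scale=10.0,
            size=n_non, random_state=rng,
        )
        dbp[non] = stats.truncnorm.rvs(
            (55 - 76) / 7.0, (90 - 76) / 7.0, loc=76, scale=7.0,
            size=n_non, random_state=rng,
        )
    return sbp, dbp, med


def _cholesterol_given_flag(flag: np.ndarray, rng) -> np.ndarray:
    n = len(flag)
    tchol = np.empty(n)
    cases = flag == 1
    n_case = int(cases.sum())
    if n_case:
        tchol[cases] = 190.0 + 0.1 + rng.gamma(1.8, 18.0, n_case)
    n_non = int((~cases).sum())
    if n_non:
        tchol[~cases] = stats.truncnorm.rvs(
            (100 - 168) / 18.0, (189.9 - 168) / 18.0, loc=168, scale=18.0,
            size=n_non, random_state=rng,
        )
    return tchol


def apply_self_report_error(
    data: pd.DataFrame, params: ErrorParams, seed: int
) -> pd.DataFrame:
    """Fill the ``sr_*`` columns from truth via the error model."""
    params.validate()
    missing = [c for c in ("true_height", "true_weight", "true_hypertension",
                           "true_hypercholesterolemia") if c not in data.columns]
    if missing:
        raise ValueError(f"truth columns missing: {missing}")
    rng = np.random.default_rng(seed)
    df = data.copy()
    n = len(df)

    female = (df["sex"] == 1).to_numpy()
    old = (df["age"] >= 65).to_numpy()
    low_edu = (df["education"] <= 2).to_numpy()
    high_edu = (df["education"] == 4).to_numpy()

    h_bias = (
        params.height_bias
        + params.height_bias_female * female
        + params.height_bias_age65 * old
        + params.height_bias_low_edu * low_edu
    )
    w_bias = (
        params.weight_bias
        + params.weight_bias_female * female
        + params.weight_bias_age65 * old
        + params.weight_bias_high_edu * high_edu
    )
    b = params.slope_attenuation
    th = df["true_height"].to_numpy()
    tw = df["true_weight"].to_numpy()
    # flat slope centred within sex: low values over-reported, high values
    # under-reported relative to the reporter's own reference group, so the
    # subgroup biases keep the sign of the intercept terms
    th_ref = np.where(female, th[female].mean(), th[~female].mean())
    tw_ref = np.where(female, tw[female].mean(), tw[~female].mean())
    df["sr_height"] = (
        th + h_bias + (b - 1.0) * (th - th_ref)
        + rng.normal(0.0, params.height_noise_sd, n)
    )
    df["sr_weight"] = (
        tw + w_bias + (b - 1.0) * (tw - tw_ref)
        + rng.normal(0.0, params.weight_noise_sd, n)
    )
    df["sr_weight"] = np.clip(df["sr_weight"], 26.0, 299.0)
    df["sr_height"] = np.clip(df["sr_height"], 101.0, 249.0)

    for cond, sens, spec in (
        ("hypertension", params.sens_hypertension, params.spec_hypertension),
        (
            "hypercholesterolemia",
            params.sens_hypercholesterolemia,
            params.spec_hypercholesterolemia,
        ),
    ):
        true_flag = df[f"true_{cond}"].to_numpy()
        p_report = np.where(true_flag == 1, sens, 1.0 - spec)
        df[f"sr_{cond}"] = (rng.random(n) < p_report).astype(float)
    return df


def misclassified_binary(true_flag, sensitivity, specificity, rng) -> np.ndarray:
    """Report 1 with probability `sensitivity` for cases and `1 - specificity`
    for non-cases — the elementary misclassification mechanism, exposed for
    direct use."""
    true_flag = np.asarray(true_flag)
    p = np.where(true_flag == 1, sensitivity, 1.0 - specificity)
    return (rng.random(len(true_flag)) < p).astype(float)


def select_validation(data: pd.DataFrame, fraction: float, seed: int) -> pd.DataFrame:
    """Completely-at-random validation subsample; measured columns are filled
    from truth inside the subsample and blanked (NaN) outside it."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("validation fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    df = data.copy()
    n = len(df)
    n_val = int(round(fraction * n))
    n_val = min(max(n_val, 1), n - 1)
    chosen = rng.choice(n, size=n_val, replace=False)
    in_val = np.zeros(n, dtype=bool)
    in_val[chosen] = True
    df["in_validation"] = in_val.astype(int)

    src = {
        "meas_height": "true_height",
        "meas_weight": "true_weight",
        "meas_sbp": "true_sbp",
        "meas_dbp": "true_dbp",
        "meas_htn_medication": "true_htn_medication",
        "meas_total_cholesterol": "true_total_cholesterol",
    }
    for meas, true in src.items():
        df[meas] = np.where(in_val, df[true], np.nan)
    return df


def assign_design(data: pd.DataFrame, params: DesignParams, seed: int) -> pd.DataFrame:
    """Assign stratum (from province), a cluster nested in the stratum, and a
    positive design weight from the weight model."""
    params.validate()
    rng = np.random.default_rng(seed)
    df = data.copy()
    df["stratum"] = df["province"].to_numpy() % params.n_strata
    df["cluster"] = df["stratum"] * params.clusters_per_stratum + rng.integers(
        0, params.clusters_per_stratum, size=len(df)
    )
    model = params.weight_model or default_weight_model
    w = np.asarray(model(df), dtype=float)
    if np.any(w <= 0) or np.any(~np.isfinite(w)):
        raise ValueError("weight_model produced non-positive or non-finite weights")
    df["weight"] = w
    return df


def generate_survey(
    truth: TruthParams | None = None,
    error: ErrorParams | None = None,
    design: DesignParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Full generator: truth -> self-report error -> design -> validation subsample.

    Sub-stage seeds are spawned from the master seed, so the whole dataset is
    reproducible bit-for-bit from (params, seed).
    """
    truth = truth or TruthParams()
    error = error or ErrorParams()
    design = design or DesignParams()
    ss = np.random.SeedSequence(seed)
    s_truth, s_err, s_design, s_val = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    ]
    df = generate_truth(truth, s_truth)
    df = apply_self_report_error(df, error, s_err)
    df = assign_design(df, design, s_design)
    df = select_validation(df, design.validation_fraction, s_val)
    return df


# ---------------------------------------------------------------------------
# serialization

def write_dataset(df: pd.DataFrame, path, seed: int | None = None, params=None):
    """CSV with empty fields for absent measured values, plus a JSON
    provenance sidecar recording the seed and generator parameters."""
    path = Path(path)
    df.to_csv(path, index=False)
    sidecar = {"seed": seed}
    if params is not None:
        sidecar["params"] = {
            k: dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
            for k, v in params.items()
            if not callable(v)
        }
    path.with_suffix(".provenance.json").write_text(json.dumps(sidecar, indent=2, default=str))


def read_dataset(path) -> pd.DataFrame:
    return pd.read_csv(path)


def params_from_yaml(path) -> dict:
    """Load TruthParams/ErrorParams/DesignParams from a YAML mapping with
    optional ``truth:``, ``error:``, ``design:`` sections."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out = {
        "truth": TruthParams(**raw.get("truth", {})),
        "error": ErrorParams(**raw.get("error", {})),
        "design": DesignParams(**raw.get("design", {})),
    }
    if "education_probs" in raw.get("truth", {}):
        out["truth"].education_probs = tuple(out["truth"].education_probs)
    return out
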