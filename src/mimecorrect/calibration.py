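"""Regression calibration: replace self-reports with model predictions.

A linear (height, weight) or logistic (hypertension, hypercholesterolemia)
model predicting the measured value from the self-report, age, sex and
education is fitted on the validation subsample.  Candidate self-report x
covariate interactions are screened forward (age, then sex, then education) and
kept when their Wald test is significant at the 5% level.  Predictive accuracy
(R^2 or AUC) is computed on a held-out 30% split; by default the selected model
is then refitted on the whole validation sample before substitution.

Calibrated continuous self-reports are predicted means; calibrated binary
self-reports are predicted probabilities, and the calibrated prevalence is
their weighted mean.  The corrected BMI is recomputed from the predicted
height and weight.  This method substitutes single predictions, so it does not
itself propagate imputation-type uncertainty into the completed values; the
standard error of a calibrated prevalence therefore carries an explicit
delta-method term for calibration-coefficient uncertainty (see
:mod:`mimecorrect.pooling`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score

from . import indicators

CONTINUOUS_OUTCOMES = {"height": "meas_height", "weight": "meas_weight"}
BINARY_OUTCOMES = {"hypertension", "hypercholesterolemia"}
SR_COLUMN = {
    "height": "sr_height",
    "weight": "sr_weight",
    "hypertension": "sr_hypertension",
    "hypercholesterolemia": "sr_hypercholesterolemia",
}
INTERACTION_ORDER = ("age", "sex", "education")
EDU_LEVELS = (1, 2, 3, 4)


@dataclass
class CalibrationModel:
    outcome: str
    family: str  # "linear" | "logistic"
    terms: list  # design-matrix column names, intercept first
    interactions: list  # accepted covariate names, subset of INTERACTION_ORDER
    coefficients: np.ndarray
    cov_params: np.ndarray
    accuracy: float  # held-out R^2 (linear) or AUC (logistic)
    accuracy_metric: str
    train_fraction: float
    n_validation: int
    seed: int

    def to_dict(self):
        return {
            "outcome": self.outcome,
            "family": self.family,
            "terms": list(self.terms),
            "interactions": list(self.interactions),
            "coefficients": [float(c) for c in self.coefficients],
            "accuracy": None if math.isnan(self.accuracy) else float(self.accuracy),
            "accuracy_metric": self.accuracy_metric,
            "train_fraction": self.train_fraction,
            "n_validation": self.n_validation,
            "seed": self.seed,
        }


def _measured_outcome(df: pd.DataFrame, outcome: str) -> np.ndarray:
    if outcome in CONTINUOUS_OUTCOMES:
        return df[CONTINUOUS_OUTCOMES[outcome]].to_numpy(dtype=float)
    ind = indicators.derive_indicators(
        df["meas_height"], df["meas_weight"],
        sbp=df["meas_sbp"], dbp=df["meas_dbp"],
        htn_medication=df["meas_htn_medication"],
        tchol=df["meas_total_cholesterol"],
    )
    return ind[outcome].to_numpy(dtype=float)


def build_design(df: pd.DataFrame, outcome: str, interactions=()) -> pd.DataFrame:
    """Design matrix: intercept, self-report, age, sex, education dummies and
    the requested self-report x covariate interaction blocks."""
    sr = df[SR_COLUMN[outcome]].to_numpy(dtype=float)
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    X["sr"] = sr
    X["age"] = df["age"].to_numpy(dtype=float)
    X["sex"] = df["sex"].to_numpy(dtype=float)
    edu = df["education"].to_numpy()
    unseen = set(np.unique(edu)) - set(EDU_LEVELS)
    if unseen:
        raise ValueError(f"unseen education levels: {sorted(unseen)}")
    for lev in EDU_LEVELS[1:]:
        X[f"edu{lev}"] = (edu == lev).astype(float)
    for cov in interactions:
        if cov == "education":
            for lev in EDU_LEVELS[1:]:
                X[f"sr:edu{lev}"] = X["sr"] * X[f"edu{lev}"]
        else:
            X[f"sr:{cov}"] = X["sr"] * X[cov]
    return X


class _FitResult:
    """Coefficients + covariance, whatever estimator produced them."""

    def __init__(self, params: np.ndarray, cov: np.ndarray, names):
        self.params = np.asarray(params, dtype=float)
        self.cov = np.asarray(cov, dtype=float)
        self.names = list(names)


def _ridge_logit(y, X: np.ndarray, lam: float = 1e-2):
    """Penalized logistic fit by Newton iterations; used when the plain MLE
    fails (perfect separation or a singular design).  The small L2 penalty
    keeps coefficients finite while leaving saturated predictions saturated."""
    n, p = X.shape
    beta = np.zeros(p)
    H = np.eye(p)
    for _ in range(200):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu) + 1e-10
        grad = X.T @ (y - mu) - lam * beta
        H = (X * w[:, None]).T @ X + lam * np.eye(p)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return beta, np.linalg.inv(H)


def _fit(y, X: pd.DataFrame, family: str) -> _FitResult:
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    if family == "linear":
        res = sm.OLS(y, X).fit()
        return _FitResult(res.params.to_numpy(), np.asarray(res.cov_params()), names)
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        params = res.params.to_numpy()
        cov = np.asarray(res.cov_params())
        if not (np.all(np.isfinite(params)) and np.all(np.isfinite(cov))):
            raise np.linalg.LinAlgError("non-finite logistic MLE")
        return _FitResult(params, cov, names)
    except Exception:
        beta, cov = _ridge_logit(np.asarray(y, dtype=float), Xv)
        return _FitResult(beta, cov, names)


def _wald_p(res: _FitResult, X_full: pd.DataFrame, cov_name: str) -> float:
    """Joint Wald test p-value for the interaction block of `cov_name`."""
    cols = (
        [f"sr:edu{l}" for l in EDU_LEVELS[1:]]
        if cov_name == "education"
        else [f"sr:{cov_name}"]
    )
    idx = [res.names.index(c) for c in cols]
    b = res.params[idx]
    V = res.cov[np.ix_(idx, idx)]
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError:
        return math.nan
    return float(stats.chi2.sf(stat, len(idx)))


def train_test_split_stratified(df, outcome, train_fraction, rng):
    """70/30-style split, stratified on the binary outcome to avoid
    single-class test sets at small n."""
    n = len(df)
    idx = np.arange(n)
    if outcome in BINARY_OUTCOMES:
        y = _measured_outcome(df, outcome)
        train_mask = np.zeros(n, dtype=bool)
        for cls in np.unique(y):
            cls_idx = idx[y == cls]
            k = int(round(train_fraction * len(cls_idx)))
            k = min(max(k, 1), len(cls_idx) - 1) if len(cls_idx) > 1 else len(cls_idx)
            train_mask[rng.choice(cls_idx, size=k, replace=False)] = True
    else:
        k = int(round(train_fraction * n))
        train_mask = np.zeros(n, dtype=bool)
        train_mask[rng.choice(idx, size=k, replace=False)] = True
    return train_mask


def fit_calibration(
    validation: pd.DataFrame,
    outcome: str,
    seed: int,
    train_fraction: float = 0.70,
    alpha: float = 0.05,
    refit_full: bool = True,
) -> CalibrationModel:
    """Fit the calibration model for one outcome on the validation subsample.

    Forward Wald screening of self-report x {age, sex, education} interactions
    on the training split, held-out accuracy on the remaining rows, then (by
    default) a refit of the selected specification on the full validation
    sample for substitution.
    """
    if outcome not in SR_COLUMN:
        raise ValueError(f"unknown outcome {outcome!r}")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    family = "linear" if outcome in CONTINUOUS_OUTCOMES else "logistic"
    df = validation.reset_index(drop=True)
    y = _measured_outcome(df, outcome)
    keep = ~np.isnan(y)
    df, y = df.loc[keep].reset_index(drop=True), y[keep]

    rng = np.random.default_rng(seed)
    train_mask = train_test_split_stratified(df, outcome, train_fraction, rng)
    df_tr, y_tr = df.loc[train_mask], y[train_mask]
    df_te, y_te = df.loc[~train_mask], y[~train_mask]

    accepted = []
    for cov in INTERACTION_ORDER:
        cand = accepted + [cov]
        X_tr = build_design(df_tr, outcome, cand)
        res = _fit(y_tr, X_tr, family)
        p = _wald_p(res, X_tr, cov)
        if np.isfinite(p) and p < alpha:
            accepted.append(cov)

    X_tr = build_design(df_tr, outcome, accepted)
    res = _fit(y_tr, X_tr, family)

    # held-out accuracy
    X_te = build_design(df_te, outcome, accepted)
    pred_te = _predict_from(res.params, X_te, family)
    if family == "linear":
        ss_res = float(np.sum((y_te - pred_te) ** 2))
        ss_tot = float(np.sum((y_te - np.mean(y_te)) ** 2))
        accuracy = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
        metric = "r2"
    else:
        if len(np.unique(y_te)) < 2:
            accuracy = math.nan  # AUC undefined on a single-class test set
        else:
            accuracy = float(roc_auc_score(y_te, pred_te))
        metric = "auc"

    if refit_full:
        X_full = build_design(df, outcome, accepted)
        res = _fit(y, X_full, family)
        terms = list(X_full.columns)
        n_fit = len(df)
    else:
        terms = list(X_tr.columns)
        n_fit = len(df_tr)

    return CalibrationModel(
        outcome=outcome,
        family=family,
        terms=terms,
        interactions=accepted,
        coefficients=res.params,
        cov_params=res.cov,
        accuracy=accuracy,
        accuracy_metric=metric,
        train_fraction=train_fraction,
        n_validation=n_fit,
        seed=seed,
    )


def _predict_from(beta, X: pd.DataFrame, family: str) -> np.ndarray:
    eta = X.to_numpy(dtype=float) @ beta
    if family == "linear":
        return eta
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -35.0, 35.0)))


def predict(model: CalibrationModel, data: pd.DataFrame) -> np.ndarray:
    """Predicted measured value (linear) or probability (logistic) for every row."""
    X = build_design(data, model.outcome, model.interactions)
    if list(X.columns) != list(model.terms):
        raise ValueError("design terms do not match the fitted model")
    return _predict_from(model.coefficients, X, model.family)


def evaluate_accuracy(
    validation: pd.DataFrame, outcome: str, seed: int, train_fraction: float = 0.70
) -> float:
    """Held-out R^2/AUC for the default calibration specification (convenience
    wrapper; the same split logic used inside :func:`fit_calibration`)."""
    return fit_calibration(
        validation, outcome, seed=seed, train_fraction=train_fraction
    ).accuracy


def calibrate_dataset(data: pd.DataFrame, models: dict) -> pd.DataFrame:
    """Substitute calibrated predictions for every respondent.

    Adds ``*_cal`` columns: predicted height/weight, BMI recomputed from them,
    overweight/obesity flags from the corrected BMI, and predicted
    probabilities for the binary conditions.
    """
    needed = {"height", "weight", "hypertension", "hypercholesterolemia"}
    missing = needed - set(models)
    if missing:
        raise ValueError(f"missing calibration models for {sorted(missing)}")
    out = data.copy()
    out["height_cal"] = predict(models["height"], data)
    out["weight_cal"] = predict(models["weight"], data)
    out["bmi_cal"] = indicators.bmi(out["weight_cal"], out["height_cal"])
    out["overweight_cal"] = indicators.overweight_flag(out["bmi_cal"])
    out["obesity_cal"] = indicators.obesity_flag(out["bmi_cal"])
    for cond in ("hypertension", "hypercholesterolemia"):
        p = predict(models[cond], data)
        if np.any((p < 0) | (p > 1)):
            raise AssertionError("logistic predictions left [0, 1]")
        out[f"{cond}_cal"] = p
    return out


def prediction_gradient(model: CalibrationModel, data: pd.DataFrame) -> np.ndarray:
    """d prediction_i / d beta — rows of the design matrix, scaled by
    p(1-p) for the logistic family.  Used by the delta-method SE of a
    calibrated prevalence."""
    X = build_design(data, model.outcome, model.interactions).to_numpy(dtype=float)
    if model.family == "linear":
        return X
    p = _predict_from(model.coefficients, build_design(data, model.outcome, model.interactions), "logistic")
    return X * (p * (1.0 - p))[:, None]
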