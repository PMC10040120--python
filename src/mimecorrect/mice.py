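"""Multiple imputation for measurement error by chained equations.

Respondents outside the validation subsample are treated as having missing
values for the measured variables; these are multiply imputed from models
fitted on the validation rows, cycling through the variables for a fixed
number of iterations.  Two imputers are provided per variable type:

* parametric — predictive mean matching (Bayesian linear-regression posterior
  draw, type-1 matching, donor draw) for continuous variables and a
  posterior-draw logistic imputer for binary ones;
* non-parametric — a donor-based random forest: each tree is grown on a
  bootstrap resample of the observed rows, a missing row is sent down one
  randomly chosen tree, and the imputed value is a uniform draw among the
  observed responses in that terminal node.  The donor draw (rather than the
  averaged forest prediction) preserves imputation variability, which the
  pooled between-imputation variance relies on.

BMI and the overweight/obesity flags are derived passively from each completed
copy's height and weight; they are never imputed directly.  Observed cells are
never overwritten.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from . import indicators

logger = logging.getLogger(__name__)

RIDGE_EPS = 1e-5

DEFAULT_TARGETS = {
    "meas_height": "continuous",
    "meas_weight": "continuous",
    "meas_hypertension": "binary",
    "meas_hypercholesterolemia": "binary",
}
SR_FOR_TARGET = {
    "meas_height": "sr_height",
    "meas_weight": "sr_weight",
    "meas_hypertension": "sr_hypertension",
    "meas_hypercholesterolemia": "sr_hypercholesterolemia",
}
BASE_COVARIATES = ["age", "sex", "education", "household_size", "province"]
CATEGORICAL = {"education", "province"}


@dataclass
class ImputationSpec:
    """Configuration of one chained-equations run.

    ``methods`` maps variable -> 'pmm' | 'logistic' | 'rf'; ``predictors``
    maps variable -> list of predictor columns.  Defaults follow the standard
    small predictor set: the self-report of the condition plus age, sex,
    education, household size and province (and wave year for multi-wave
    data).  ``m`` completed datasets, ``n_iterations`` sweeps, ``n_trees``
    per forest, ``pmm_donors`` candidate donors.
    """

    methods: dict = field(default_factory=dict)
    predictors: dict = field(default_factory=dict)
    m: int = 10
    n_iterations: int = 100
    n_trees: int = 100
    pmm_donors: int = 5
    visit_sequence: list = field(default_factory=list)
    seed: int = 0

    def validate(self, data: pd.DataFrame):
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.n_iterations < 1 or self.n_trees < 1 or self.pmm_donors < 1:
            raise ValueError("n_iterations, n_trees and pmm_donors must be >= 1")
        for var, preds in self.predictors.items():
            for p in preds:
                if p not in data.columns:
                    raise ValueError(f"predictor {p!r} for {var!r} not in dataset")


def default_spec(approach: str = "rf", data: pd.DataFrame | None = None, **over) -> ImputationSpec:
    """Spec for the standard four measured targets.

    ``approach='parametric'`` uses PMM for continuous and logistic for binary
    targets; ``approach='rf'`` uses the random forest for all.  Keyword
    overrides are passed straight to :class:`ImputationSpec`.
    """
    if approach == "parametric":
        methods = {
            "meas_height": "pmm",
            "meas_weight": "pmm",
            "meas_hypertension": "logistic",
            "meas_hypercholesterolemia": "logistic",
        }
    elif approach == "rf":
        methods = {v: "rf" for v in DEFAULT_TARGETS}
    else:
        raise ValueError("approach must be 'parametric' or 'rf'")
    preds = {}
    covs = list(BASE_COVARIATES)
    if data is not None and "wave_year" in data.columns and data["wave_year"].nunique() > 1:
        covs.append("wave_year")
    for var in DEFAULT_TARGETS:
        preds[var] = [SR_FOR_TARGET[var]] + covs
    kwargs = {"methods": methods, "predictors": preds}
    kwargs.update(over)
    return ImputationSpec(**kwargs)


@dataclass
class CompletedSet:
    """The m completed datasets plus provenance."""

    datasets: list
    spec: ImputationSpec
    trace: pd.DataFrame

    @property
    def m(self):
        return len(self.datasets)


# ---------------------------------------------------------------------------
# elementary imputers

def _as_matrix(X):
    X = np.asarray(X, dtype=float)
    return X.reshape(len(X), -1)


def bayes_linear_draw(y_obs, X_obs, rng):
    """Posterior-mean coefficients, a coefficient draw and a sigma draw for a
    normal linear model (ridge-stabilised normal-inverse-chi-square
    approximation)."""
    X = _as_matrix(X_obs)
    y = np.asarray(y_obs, dtype=float)
    n, p = X.shape
    xtx = X.T @ X + RIDGE_EPS * np.eye(p)
    xty = X.T @ y
    beta_hat = np.linalg.solve(xtx, xty)
    resid = y - X @ beta_hat
    df = max(n - p, 1)
    sigma2_draw = float(resid @ resid) / stats.chi2.rvs(df, random_state=rng)
    V = np.linalg.inv(xtx)
    L = np.linalg.cholesky((V + V.T) / 2.0)
    beta_draw = beta_hat + math.sqrt(sigma2_draw) * (L @ rng.standard_normal(p))
    return beta_hat, beta_draw, sigma2_draw


def impute_pmm(y_obs, X_obs, X_mis, donors, rng):
    """Predictive mean matching (type 1).

    Observed rows are ranked by posterior-mean predictions, missing rows by
    drawn-coefficient predictions; each missing row receives the observed y of
    one of its ``donors`` closest observed rows, drawn uniformly.  Every
    imputed value is therefore a member of the observed-value set.
    """
    y = np.asarray(y_obs, dtype=float)
    X_obs, X_mis = _as_matrix(X_obs), _as_matrix(X_mis)
    if len(X_mis) == 0:
        return np.empty(0)
    if X_obs.shape[0] <= X_obs.shape[1]:
        raise ValueError("need more observed rows than predictors for PMM")
    if np.allclose(y, y[0]):
        return np.full(len(X_mis), y[0])
    beta_hat, beta_draw, _ = bayes_linear_draw(y, X_obs, rng)
    yhat_obs = X_obs @ beta_hat
    yhat_mis = X_mis @ beta_draw
    k = min(int(donors), len(y))
    # distance matrix donors: n_mis x n_obs; fine at survey scale
    d = np.abs(yhat_obs[None, :] - yhat_mis[:, None])
    nearest = np.argpartition(d, k - 1, axis=1)[:, :k]
    pick = rng.integers(0, k, size=len(X_mis))
    return y[nearest[np.arange(len(X_mis)), pick]]


def impute_logistic(y_obs, X_obs, X_mis, rng):
    """Binary imputation by a posterior draw of logistic coefficients.

    Falls back to shrunken-prevalence Bernoulli draws when only one class is
    observed, and to PMM on the linear-probability score when the logistic fit
    fails (separation / singular design).
    """
    y = np.asarray(y_obs, dtype=float)
    X_obs, X_mis = _as_matrix(X_obs), _as_matrix(X_mis)
    if len(X_mis) == 0:
        return np.empty(0)
    classes = np.unique(y)
    if len(classes) < 2:
        n = len(y)
        s = float(np.sum(y))
        p_star = stats.beta.rvs(s + 0.5, n - s + 0.5, random_state=rng)
        logger.warning("single-class outcome in logistic imputer; prevalence fallback")
        return (rng.random(len(X_mis)) < p_star).astype(float)
    try:
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            res = sm.Logit(y, X_obs).fit(disp=0, maxiter=100)
        beta_hat = np.asarray(res.params, dtype=float)
        cov = np.asarray(res.cov_params(), dtype=float)
        if not np.all(np.isfinite(beta_hat)) or not np.all(np.isfinite(cov)):
            raise np.linalg.LinAlgError("non-finite logistic fit")
        L = np.linalg.cholesky((cov + cov.T) / 2.0 + RIDGE_EPS * np.eye(len(beta_hat)))
    except Exception:
        # separation or singular design: ridge-penalized fit keeps the draw proper
        from .calibration import _ridge_logit

        logger.debug("plain logistic fit failed; using ridge-penalized fit")
        beta_hat, cov = _ridge_logit(y, X_obs)
        L = np.linalg.cholesky((cov + cov.T) / 2.0 + RIDGE_EPS * np.eye(len(beta_hat)))
    beta_draw = beta_hat + L @ rng.standard_normal(len(beta_hat))
    eta = np.clip(X_mis @ beta_draw, -35.0, 35.0)
    p_mis = 1.0 / (1.0 + np.exp(-eta))
    return (rng.random(len(X_mis)) < p_mis).astype(float)


def impute_rf(
    y_obs, X_obs, X_mis, n_trees, rng, binary=False, min_samples_leaf=None, proper=True
):
    """Donor-based random-forest imputation.

    Trees are fitted on bootstrap resamples of the observed rows; a missing
    row is dropped down one randomly chosen tree and imputed by a uniform draw
    among the in-bag observed responses in its terminal node.  Continuous
    imputations are therefore always members of the observed-value set.

    With ``proper=True`` (default) the whole forest is additionally fitted on
    an outer bootstrap resample of the observed rows, redrawn on every call.
    This is the nonparametric analogue of the Bayesian coefficient draw in
    PMM: it injects the sampling uncertainty of the observed (validation)
    rows into each imputation, so the between-imputation variance of pooled
    estimates reflects it.  Without it, per-row random tree choice averages
    the model uncertainty away across rows and pooled standard errors are
    badly underestimated when the share of missing rows is large.
    """
    y = np.asarray(y_obs, dtype=float)
    X_obs, X_mis = _as_matrix(X_obs), _as_matrix(X_mis)
    n_mis = len(X_mis)
    if n_mis == 0:
        return np.empty(0)
    if len(y) < 2:
        raise ValueError("random-forest imputation needs >= 2 observed rows")
    if np.allclose(y, y[0]):
        return np.full(n_mis, y[0])
    n_obs = len(y)
    if proper:
        boot = rng.integers(0, n_obs, n_obs)
        X_fit, y_fit = X_obs[boot], y[boot]
        if np.allclose(y_fit, y_fit[0]):  # degenerate resample of a rare class
            return np.full(n_mis, y_fit[0])
    else:
        X_fit, y_fit = X_obs, y

    n_feat = X_fit.shape[1]
    # mtry p/3 throughout (regression convention); with dummy-coded survey
    # covariates the sqrt(p) classification default starves weak gradients
    # (e.g. an age trend) of split opportunities against categorical noise
    mtry = max(1, n_feat // 3)
    if min_samples_leaf is None:
        min_samples_leaf = 1 if binary else 5
    cls = DecisionTreeClassifier if binary else DecisionTreeRegressor
    tree_pick = rng.integers(0, int(n_trees), size=n_mis)
    out = np.empty(n_mis)
    for t in np.unique(tree_pick):
        inbag = rng.integers(0, n_obs, n_obs)  # per-tree bootstrap resample
        X_t, y_t = X_fit[inbag], y_fit[inbag]
        tree = cls(
            min_samples_leaf=min_samples_leaf,
            max_features=mtry,
            random_state=int(rng.integers(2**31 - 1)),
        )
        tree.fit(X_t, y_t.astype(int) if binary else y_t)
        leaves_inbag = tree.apply(X_t)
        rows = np.flatnonzero(tree_pick == t)
        leaves_mis = tree.apply(X_mis[rows])
        # group in-bag donors by terminal node
        order = np.argsort(leaves_inbag, kind="stable")
        sorted_leaves = leaves_inbag[order]
        y_inbag_sorted = y_t[order]
        starts = np.searchsorted(sorted_leaves, leaves_mis, side="left")
        ends = np.searchsorted(sorted_leaves, leaves_mis, side="right")
        # every leaf of a fitted tree contains at least one in-bag row
        picks = starts + (rng.random(len(rows)) * (ends - starts)).astype(int)
        out[rows] = y_inbag_sorted[picks]
    return out


# ---------------------------------------------------------------------------
# chained engine

def prepare_imputation_frame(data: pd.DataFrame) -> pd.DataFrame:
    """Add directly-imputable binary measured indicators derived from the
    examination measurements (threshold logic) where they are observed."""
    df = data.copy()
    if "meas_hypertension" not in df.columns and "meas_sbp" in df.columns:
        df["meas_hypertension"] = indicators.hypertension_flag(
            df["meas_sbp"], df["meas_dbp"], df["meas_htn_medication"]
        )
    if (
        "meas_hypercholesterolemia" not in df.columns
        and "meas_total_cholesterol" in df.columns
    ):
        df["meas_hypercholesterolemia"] = indicators.hypercholesterolemia_flag(
            df["meas_total_cholesterol"]
        )
    return df


def _encode_predictors(df: pd.DataFrame, predictors) -> np.ndarray:
    """Design matrix with intercept; categorical covariates are dummy-coded."""
    cols = [np.ones(len(df))]
    for p in predictors:
        v = df[p]
        if p in CATEGORICAL:
            levels = np.sort(v.dropna().unique())
            for lev in levels[1:]:
                cols.append((v == lev).to_numpy(dtype=float))
        else:
            cols.append(v.to_numpy(dtype=float))
    return np.column_stack(cols)


def initialize_chains(data: pd.DataFrame, spec: ImputationSpec, rngs) -> list:
    """Starting state per chain: missing cells filled by draws from the
    variable's observed values."""
    states = []
    masks = {v: data[v].isna().to_numpy() for v in spec.methods if v in data.columns}
    for var, mask in masks.items():
        if mask.all():
            raise ValueError(f"variable {var!r} has no observed values")
    for rng in rngs:
        df = data.copy()
        for var, mask in masks.items():
            obs = df.loc[~mask, var].to_numpy()
            df.loc[mask, var] = rng.choice(obs, size=int(mask.sum()), replace=True)
        states.append(df)
    return states


def _impute_one(method, var_type, y_obs, X_obs, X_mis, spec, rng):
    if method == "pmm":
        return impute_pmm(y_obs, X_obs, X_mis, spec.pmm_donors, rng)
    if method == "logistic":
        return impute_logistic(y_obs, X_obs, X_mis, rng)
    if method == "rf":
        return impute_rf(
            y_obs, X_obs, X_mis, spec.n_trees, rng, binary=(var_type == "binary")
        )
    raise ValueError(f"unknown imputation method {method!r}")


def run_chained(data: pd.DataFrame, spec: ImputationSpec):
    """Run the chained-equations algorithm.

    Returns a :class:`CompletedSet` (m completed copies with passively derived
    BMI/overweight/obesity) and fills the per-chain x iteration x variable
    trace of imputed-value means and SDs.
    """
    df0 = prepare_imputation_frame(data).reset_index(drop=True)
    spec.validate(df0)
    targets = {v: m for v, m in spec.methods.items() if v in df0.columns}
    masks = {v: df0[v].isna().to_numpy() for v in targets}
    to_impute = [v for v in targets if masks[v].any()]

    visit = list(spec.visit_sequence) if spec.visit_sequence else sorted(
        to_impute, key=lambda v: masks[v].sum()
    )  # most-missing last
    var_types = {
        v: ("binary" if set(df0[v].dropna().unique()) <= {0.0, 1.0} else "continuous")
        for v in to_impute
    }

    ss = np.random.SeedSequence(spec.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(spec.m)]

    trace_rows = []
    completed = []
    if not to_impute:
        trace = pd.DataFrame(columns=["chain", "iteration", "variable", "mean", "sd"])
        return CompletedSet([_derive_passive(df0) for _ in range(spec.m)], spec, trace)

    # predictor matrices are constant across iterations unless a predictor is
    # itself imputed in this run
    static_X = {}
    for v in visit:
        preds = spec.predictors.get(v, [SR_FOR_TARGET.get(v, v)] + BASE_COVARIATES)
        if not any(p in to_impute or df0[p].isna().any() for p in preds):
            static_X[v] = _encode_predictors(df0, preds)

    states = initialize_chains(df0, spec, rngs)
    for chain, (df, rng) in enumerate(zip(states, rngs)):
        for it in range(spec.n_iterations):
            for var in visit:
                preds = spec.predictors.get(
                    var, [SR_FOR_TARGET.get(var, var)] + BASE_COVARIATES
                )
                mask = masks[var]
                X = static_X.get(var)
                if X is None:
                    X = _encode_predictors(df, preds)
                y_obs = df0.loc[~mask, var].to_numpy(dtype=float)
                imputed = _impute_one(
                    targets[var], var_types[var], y_obs, X[~mask], X[mask], spec, rng
                )
                if not np.all(np.isfinite(imputed)):
                    raise RuntimeError(
                        f"divergent imputations for {var!r} at iteration {it}"
                    )
                df.loc[mask, var] = imputed
                trace_rows.append(
                    {
                        "chain": chain,
                        "iteration": it,
                        "variable": var,
                        "mean": float(np.mean(imputed)),
                        "sd": float(np.std(imputed, ddof=1)) if len(imputed) > 1 else 0.0,
                    }
                )
        completed.append(_derive_passive(df))
    trace = pd.DataFrame(trace_rows)
    return CompletedSet(completed, spec, trace)


def _derive_passive(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    if "meas_height" in out.columns and "meas_weight" in out.columns:
        h = out["meas_height"].to_numpy(dtype=float)
        w = out["meas_weight"].to_numpy(dtype=float)
        if not np.any(np.isnan(h)) and not np.any(np.isnan(w)):
            out["bmi_completed"] = indicators.bmi(w, h)
            out["overweight_completed"] = indicators.overweight_flag(out["bmi_completed"])
            out["obesity_completed"] = indicators.obesity_flag(out["bmi_completed"])
    return out


# ---------------------------------------------------------------------------
# convergence diagnostics

def convergence_summary(
    trace: pd.DataFrame, window: int, threshold: float = 1.2
) -> pd.DataFrame:
    """Between- vs within-chain stability of the imputed-value means over the
    final ``window`` iterations, summarised as a potential-scale-reduction
    style ratio per variable; ``flag`` marks variables exceeding ``threshold``.
    """
    if trace.empty:
        raise ValueError("empty trace")
    n_iter = trace["iteration"].max() + 1
    if n_iter < 2:
        raise ValueError("need at least 2 logged iterations")
    if window > n_iter:
        raise ValueError("window longer than the logged chain")
    rows = []
    tail = trace[trace["iteration"] >= n_iter - window]
    for var, g in tail.groupby("variable"):
        pivot = g.pivot_table(index="iteration", columns="chain", values="mean")
        w = len(pivot)
        chain_means = pivot.mean(axis=0).to_numpy()
        within = pivot.var(axis=0, ddof=1).mean()
        between = w * np.var(chain_means, ddof=1)
        if within <= 0:
            rhat = 1.0 if between <= 1e-12 else math.inf
        else:
            var_plus = (w - 1) / w * within + between / w
            rhat = math.sqrt(var_plus / within)
        rows.append({"variable": var, "rhat": float(rhat), "flag": bool(rhat > threshold)})
    return pd.DataFrame(rows)
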