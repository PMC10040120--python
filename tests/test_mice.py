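"""Chained-equations engine: elementary imputers, chain mechanics, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mimecorrect as mc
from mimecorrect import indicators, mice


def _toy_xy(rng, n_obs=40, n_mis=15, p=3):
    X = np.column_stack([np.ones(n_obs + n_mis), rng.normal(size=(n_obs + n_mis, p))])
    y = X[:, 1] * 2.0 + rng.normal(0, 0.5, n_obs + n_mis)
    return y[:n_obs], X[:n_obs], X[n_obs:]


class TestPMM:
    def test_constant_outcome(self, rng):
        _, X_obs, X_mis = _toy_xy(rng)
        out = mice.impute_pmm(np.full(40, 7.5), X_obs, X_mis, donors=5, rng=rng)
        assert np.all(out == 7.5)

    def test_donor_membership(self, rng):
        y, X_obs, X_mis = _toy_xy(rng)
        out = mice.impute_pmm(y, X_obs, X_mis, donors=5, rng=rng)
        assert np.all(np.isin(out, y))

    def test_single_donor_exact_match(self):
        """donors=1 on a noiseless linear relation: a missing x coinciding with
        an observed x must receive that row's y, for every seed."""
        x_obs = np.arange(1.0, 11.0)
        y_obs = 2.0 * x_obs
        X_obs = np.column_stack([np.ones(10), x_obs])
        X_mis = np.array([[1.0, 4.0]])
        for seed in range(30):
            out = mice.impute_pmm(
                y_obs, X_obs, X_mis, donors=1, rng=np.random.default_rng(seed)
            )
            assert out[0] == 8.0

    def test_underdetermined_rejected(self, rng):
        X = np.ones((3, 5))
        with pytest.raises(ValueError):
            mice.impute_pmm(np.array([1.0, 2.0, 3.0]), X, X, donors=3, rng=rng)


class TestLogistic:
    def test_single_class_fallback(self, rng):
        y = np.zeros(30)
        X = np.ones((30, 1))
        out = mice.impute_logistic(y, X, np.ones((500, 1)), rng)
        assert out.mean() < 0.1  # shrunken prevalence near 0

    def test_marginal_draw_identity(self, rng):
        """Covariate-free model with prevalence 0.4 imputes ~0.4."""
        y = (rng.random(400) < 0.4).astype(float)
        X = np.ones((400, 1))
        draws = mice.impute_logistic(y, X, np.ones((2000, 1)), rng)
        assert draws.mean() == pytest.approx(y.mean(), abs=0.08)

    def test_strong_predictor_monotonicity(self, rng):
        """A strongly positive predictor raises imputed probability for
        high-predictor rows (aggregated over replicates)."""
        hi, lo = [], []
        for rep in range(50):
            r = np.random.default_rng(rep)
            x = r.normal(size=200)
            p = 1 / (1 + np.exp(-3 * x))
            y = (r.random(200) < p).astype(float)
            X = np.column_stack([np.ones(200), x])
            X_mis = np.array([[1.0, 2.0], [1.0, -2.0]])
            out = mice.impute_logistic(y, X, X_mis, r)
            hi.append(out[0])
            lo.append(out[1])
        assert np.mean(hi) > 0.8 > 0.2 > np.mean(lo)


class TestRF:
    def test_constant_outcome(self, rng):
        _, X_obs, X_mis = _toy_xy(rng)
        out = mice.impute_rf(np.full(40, 3.3), X_obs, X_mis, 10, rng)
        assert np.all(out == 3.3)

    def test_donor_membership(self, rng):
        y, X_obs, X_mis = _toy_xy(rng)
        out = mice.impute_rf(y, X_obs, X_mis, 10, rng)
        assert np.all(np.isin(out, y))

    def test_step_function_recovery(self):
        """y is a step in one binary feature; with deep trees the imputations
        match the step level of each missing row almost always."""
        x = np.repeat([0.0, 1.0], 40)
        y = np.where(x == 1, 10.0, -10.0)
        X = np.column_stack([np.ones(80), x])
        X_mis = np.column_stack([np.ones(20), np.repeat([0.0, 1.0], 10)])
        hits = 0
        for seed in range(20):
            out = mice.impute_rf(
                y, X, X_mis, 30, np.random.default_rng(seed), min_samples_leaf=1
            )
            hits += np.mean(out == np.where(X_mis[:, 1] == 1, 10.0, -10.0))
        assert hits / 20 > 0.95

    def test_binary_mode_returns_flags(self, rng):
        y = (rng.random(60) < 0.3).astype(float)
        X = np.column_stack([np.ones(60), rng.normal(size=60)])
        out = mice.impute_rf(y, X, X[:10], 10, rng, binary=True)
        assert set(np.unique(out)) <= {0.0, 1.0}


@settings(max_examples=120, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 2**20),
    n_obs=st.integers(12, 60),
    n_mis=st.integers(1, 25),
    donors=st.integers(1, 8),
)
def test_continuous_imputations_always_donor_values(seed, n_obs, n_mis, donors):
    """Property: PMM and RF continuous imputations are members of the
    observed-value set, hence inside the observed range."""
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n_obs + n_mis), rng.normal(size=(n_obs + n_mis, 2))])
    y = 1.5 * X[:, 1] - X[:, 2] + rng.normal(0, 1, n_obs + n_mis)
    y_obs, X_obs, X_mis = y[:n_obs], X[:n_obs], X[n_obs:]
    pmm = mice.impute_pmm(y_obs, X_obs, X_mis, donors=donors, rng=rng)
    rf = mice.impute_rf(y_obs, X_obs, X_mis, 5, rng)
    assert np.all(np.isin(pmm, y_obs))
    assert np.all(np.isin(rf, y_obs))


@pytest.fixture(scope="module")
def survey():
    return mc.generate_survey(
        mc.TruthParams(n_respondents=600),
        design=mc.DesignParams(validation_fraction=0.3),
        seed=31,
    )


@pytest.fixture(scope="module")
def completed_rf(survey):
    spec = mice.default_spec("rf", data=survey, m=3, n_iterations=3,
                             n_trees=10, seed=5)
    return mice.run_chained(survey, spec)


class TestChainedRun:
    def test_no_missing_cells_remain(self, completed_rf):
        for d in completed_rf.datasets:
            for var in mice.DEFAULT_TARGETS:
                assert d[var].notna().all()

    def test_observed_cells_never_overwritten(self, survey, completed_rf):
        prepared = mice.prepare_imputation_frame(survey).reset_index(drop=True)
        obs = prepared["in_validation"] == 1
        for d in completed_rf.datasets:
            for var in mice.DEFAULT_TARGETS:
                np.testing.assert_allclose(
                    d.loc[obs.to_numpy(), var], prepared.loc[obs, var]
                )

    def test_passive_consistency(self, completed_rf):
        """Overweight/obesity in every completed copy equal the BMI thresholds
        applied to that copy's height and weight."""
        for d in completed_rf.datasets:
            b = indicators.bmi(d["meas_weight"], d["meas_height"])
            np.testing.assert_allclose(d["bmi_completed"], b)
            np.testing.assert_array_equal(
                d["overweight_completed"], indicators.overweight_flag(b)
            )
            np.testing.assert_array_equal(
                d["obesity_completed"], indicators.obesity_flag(b)
            )

    def test_determinism(self, survey):
        spec = mice.default_spec("parametric", data=survey, m=2, n_iterations=2, seed=9)
        a = mice.run_chained(survey, spec)
        b = mice.run_chained(survey, spec)
        for da, db in zip(a.datasets, b.datasets):
            pd.testing.assert_frame_equal(da, db)
        pd.testing.assert_frame_equal(a.trace, b.trace)

    def test_zero_missing_returns_identical_copies(self, survey):
        full = survey[survey["in_validation"] == 1].copy()
        spec = mice.default_spec("parametric", data=full, m=3, n_iterations=2, seed=2)
        out = mice.run_chained(full, spec)
        assert out.trace.empty
        prepared = mice.prepare_imputation_frame(full).reset_index(drop=True)
        for d in out.datasets:
            for var in mice.DEFAULT_TARGETS:
                np.testing.assert_allclose(d[var], prepared[var])

    def test_covariate_missingness_imputed_in_same_process(self, survey):
        """Item nonresponse in a covariate is imputed alongside the targets."""
        df = survey.copy().reset_index(drop=True)
        rng = np.random.default_rng(0)
        holes = rng.choice(len(df), 40, replace=False)
        df.loc[holes, "household_size"] = np.nan
        spec = mice.default_spec("parametric", data=df, m=2, n_iterations=2, seed=3)
        spec.methods["household_size"] = "pmm"
        spec.predictors["household_size"] = ["age", "sex", "education"]
        out = mice.run_chained(df, spec)
        for d in out.datasets:
            assert d["household_size"].notna().all()
            assert np.all(np.isin(d.loc[holes, "household_size"],
                                  df["household_size"].dropna().unique()))

    def test_fully_missing_variable_rejected(self, survey):
        df = survey.copy()
        df["meas_height"] = np.nan
        spec = mice.default_spec("rf", data=df, m=2, n_iterations=1, seed=1)
        with pytest.raises(ValueError, match="no observed values"):
            mice.run_chained(df, spec)

    def test_invalid_spec_rejected(self, survey):
        with pytest.raises(ValueError):
            mice.default_spec("rf", data=survey, m=1).validate(survey)
        spec = mice.default_spec("rf", data=survey)
        spec.predictors["meas_height"] = ["not_a_column"]
        with pytest.raises(ValueError, match="not_a_column"):
            spec.validate(survey)


class TestConvergence:
    @staticmethod
    def _trace(chains, iterations, shift_chain=None):
        rows = []
        rng = np.random.default_rng(0)
        for c in range(chains):
            for i in range(iterations):
                mean = 10.0 + rng.normal(0, 0.1)
                if shift_chain is not None and c == shift_chain:
                    mean += 25.0
                rows.append(
                    {"chain": c, "iteration": i, "variable": "v", "mean": mean, "sd": 1.0}
                )
        return pd.DataFrame(rows)

    def test_identical_chains_no_flag(self):
        t = self._trace(4, 20)
        t["mean"] = 10.0
        out = mice.convergence_summary(t, window=10)
        assert not out["flag"].any()
        assert out["rhat"].iloc[0] == pytest.approx(1.0)

    def test_shifted_chain_flagged(self):
        out = mice.convergence_summary(self._trace(4, 20, shift_chain=0), window=10)
        assert out["flag"].all()

    def test_window_longer_than_chain_rejected(self):
        with pytest.raises(ValueError):
            mice.convergence_summary(self._trace(3, 5), window=10)
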