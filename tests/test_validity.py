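"""Agreement-metric oracles and invariants."""

import math

import numpy as np
import pytest

import mimecorrect as mc
from mimecorrect import validity

# fixed 6-pair fixture for the ICC oracle checks
ICC_SELF = np.array([170.0, 165.0, 180.0, 158.0, 172.0, 169.0])
ICC_MEAS = np.array([168.0, 166.0, 175.0, 160.0, 171.0, 165.0])


def _anova_icc_oracle(a, b):
    """Brute-force two-way absolute-agreement single-measure ICC via explicit
    ANOVA sums of squares (independent of the implementation under test)."""
    Y = np.column_stack([a, b])
    n, k = Y.shape
    grand = Y.mean()
    msr = k * sum((Y[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((Y[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (Y[i, j] - Y[i].mean() - Y[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestBlandAltman:
    def test_hand_computed_limits(self):
        """Differences {-2, 0, 2}: mean 0, sample SD 2, limits ±3.92."""
        rep = validity.bland_altman([8.0, 10.0, 12.0], [10.0, 10.0, 10.0])
        assert rep.mean_diff == pytest.approx(0.0)
        assert rep.loa_upper == pytest.approx(3.92)
        assert rep.loa_lower == pytest.approx(-3.92)

    def test_identical_pairs_zero_band(self):
        rep = validity.bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.mean_diff == rep.loa_lower == rep.loa_upper == 0.0

    def test_weight_scale_invariance(self, rng):
        a = rng.normal(170, 6, 50)
        b = a + rng.normal(1, 2, 50)
        w = rng.uniform(0.5, 3.0, 50)
        r1 = validity.bland_altman(a, b, weights=w)
        r2 = validity.bland_altman(a, b, weights=2 * w)
        assert r1.mean_diff == pytest.approx(r2.mean_diff)
        assert r1.loa_upper == pytest.approx(r2.loa_upper)

    def test_loa_symmetry_invariant(self, rng):
        a = rng.normal(80, 10, 40)
        b = a + rng.normal(-1.5, 3, 40)
        rep = validity.bland_altman(a, b)
        assert rep.loa_upper - rep.mean_diff == pytest.approx(
            rep.mean_diff - rep.loa_lower
        )

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            validity.bland_altman([1.0], [2.0])


class TestPairedT:
    def test_textbook_oracle(self):
        """Differences {1,2,3,4}: t = dbar / (sd/sqrt(n))."""
        meas = np.array([10.0, 20.0, 30.0, 40.0])
        self_v = meas + np.array([1.0, 2.0, 3.0, 4.0])
        out = validity.paired_mean_difference_test(self_v, meas)
        d = np.array([1.0, 2.0, 3.0, 4.0])
        t_oracle = d.mean() / (d.std(ddof=1) / math.sqrt(4))
        assert out["t"] == pytest.approx(t_oracle)
        assert not out["degenerate"]

    def test_zero_variance_degenerate(self):
        out = validity.paired_mean_difference_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert out["degenerate"]
        assert math.isnan(out["p"])

    def test_ci_p_duality(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, 15)
            b = a + rng.normal(0.3, 1, 15)
            out = validity.paired_mean_difference_test(a, b)
            excludes_zero = out["ci"][0] > 0 or out["ci"][1] < 0
            assert excludes_zero == (out["p"] < 0.05)


class TestICC:
    def test_perfect_agreement(self):
        icc, _ = validity.icc_agreement([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert icc == pytest.approx(1.0)

    def test_fixture_matches_anova_oracle(self):
        icc, _ = validity.icc_agreement(ICC_SELF, ICC_MEAS)
        assert icc == pytest.approx(_anova_icc_oracle(ICC_SELF, ICC_MEAS), abs=1e-12)

    def test_fixture_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        n = len(ICC_SELF)
        long = pd.DataFrame(
            {
                "targets": list(range(n)) * 2,
                "raters": ["self"] * n + ["meas"] * n,
                "score": np.concatenate([ICC_SELF, ICC_MEAS]),
            }
        )
        ref = pg.intraclass_corr(long, "targets", "raters", "score")
        mask = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        icc2 = float(ref.loc[mask, "ICC"].iloc[0])
        icc, ci = validity.icc_agreement(ICC_SELF, ICC_MEAS)
        assert icc == pytest.approx(icc2, abs=1e-9)
        assert icc == pytest.approx(0.895449, abs=1e-6)  # frozen oracle value
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        ref_ci = ref.loc[mask, ci_col].iloc[0]
        assert ci[0] == pytest.approx(ref_ci[0], abs=0.02)  # pingouin rounds
        assert ci[1] == pytest.approx(ref_ci[1], abs=0.02)

    def test_offset_strictly_decreases_agreement(self):
        base, _ = validity.icc_agreement(ICC_SELF, ICC_MEAS)
        shifted, _ = validity.icc_agreement(ICC_SELF + 4.0, ICC_MEAS)
        assert shifted < base


class TestConfusion:
    def test_hand_arithmetic(self):
        a = np.concatenate([np.ones(30), np.zeros(10), np.ones(5), np.zeros(55)])
        b = np.concatenate([np.ones(40), np.zeros(60)])
        s = validity.confusion(a, b)
        assert s.sensitivity == pytest.approx(0.75)
        assert s.specificity == pytest.approx(55 / 60)
        assert s.ppv == pytest.approx(30 / 35)
        assert s.npv == pytest.approx(55 / 65)

    def test_kappa_hand_oracle(self):
        """Agreement table [[40,10],[10,40]]: p_o 0.8, p_e 0.5, kappa 0.6."""
        assert validity.cohen_kappa([[40, 10], [10, 40]]) == pytest.approx(0.6)

    def test_kappa_perfect_and_label_swap(self, rng):
        a = (rng.random(80) < 0.4).astype(float)
        s = validity.confusion(a, a)
        assert s.kappa == pytest.approx(1.0)
        b = (rng.random(80) < 0.5).astype(float)
        k1 = validity.confusion(a, b).kappa
        k2 = validity.confusion(1 - a, 1 - b).kappa
        assert k1 == pytest.approx(k2)

    def test_mcnemar_symmetry_and_oracle(self):
        # b = c discordant: statistic 0
        a = np.array([1.0, 0.0, 1.0, 0.0])
        b = np.array([0.0, 1.0, 1.0, 0.0])
        assert validity.confusion(a, b).mcnemar_stat == 0.0
        # b=10, c=20 -> (10-20)^2/30
        a = np.concatenate([np.ones(10), np.zeros(20), np.ones(5), np.zeros(5)])
        b = np.concatenate([np.zeros(10), np.ones(20), np.ones(5), np.zeros(5)])
        assert validity.confusion(a, b).mcnemar_stat == pytest.approx(10.0 / 3.0)

    def test_empty_margin_undefined_not_zero(self):
        a = np.array([0.0, 0.0, 1.0])
        b = np.array([0.0, 0.0, 0.0])  # no measured positives
        s = validity.confusion(a, b)
        assert math.isnan(s.sensitivity)
        assert not math.isnan(s.specificity)


class TestStratified:
    def test_partition_conservation(self, small_survey):
        reports = validity.stratified_validity(
            small_survey, "hypertension", "sex", weighted=True
        )
        whole = reports[0]
        parts = reports[1:]
        assert len(parts) == 2
        for fieldname in ("tp", "fp", "fn", "tn"):
            total = sum(getattr(p, fieldname) for p in parts)
            assert total == pytest.approx(getattr(whole, fieldname), rel=1e-9)

    def test_unknown_stratum_rejected(self, small_survey):
        with pytest.raises(ValueError):
            validity.stratified_validity(small_survey, "bmi", "province_group")

    def test_continuous_variable_reports(self, small_survey):
        reports = validity.stratified_validity(small_survey, "bmi", "age_band")
        assert reports[0].stratum == "all"
        assert reports[0].mean_diff < 0  # BMI under-reported on average
        assert all(r.loa_lower <= r.mean_diff <= r.loa_upper for r in reports)

    def test_sex_specific_height_bias_direction(self, midsize_survey):
        """Generator injects a larger female height over-report; the stratified
        analysis should recover the ordering."""
        reports = validity.stratified_validity(midsize_survey, "height", "sex")
        by = {r.stratum: r for r in reports}
        assert by["female"].mean_diff > by["male"].mean_diff > 0
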