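"""Benchmark statistics: AD scores, regression fits, ICC, grouped reports."""

import numpy as np
import pytest

from voiceonset import ad_scores, evaluate, grouped_report, icc, regression_fit
from voiceonset.evaluation import (
    DegenerateRegressionError,
    IncompleteDesignError,
    PairingError,
)


class TestADScores:
    def test_perfect_agreement(self):
        s = ad_scores([100.0, 200.0], [100.0, 200.0])
        assert s.prop_within_10ms == 1.0
        assert s.sd_abs == 0.0

    def test_half_within_10ms(self):
        s = ad_scores([100.0, 200.0], [105.0, 260.0])
        np.testing.assert_allclose(np.abs(s.differences), [5.0, 60.0])
        assert s.prop_within_10ms == 0.5

    def test_cdf_reaches_one_at_max(self):
        s = ad_scores([100.0, 200.0, 300.0], [90.0, 230.0, 310.0])
        assert s.cdf[-1] == 1.0

    def test_undetected_pairs_excluded_and_counted(self):
        s = ad_scores([100.0, 200.0, 300.0], [100.0, np.nan, 300.0])
        assert s.n_excluded == 1
        assert s.differences.size == 2

    def test_length_mismatch_raises(self):
        with pytest.raises(PairingError):
            ad_scores([1.0, 2.0], [1.0])


class TestRegressionFit:
    def test_identity_fit(self):
        r = regression_fit([100.0, 200.0, 300.0], [100.0, 200.0, 300.0])
        assert r.r_squared == pytest.approx(1.0)
        assert r.offset == pytest.approx(0.0, abs=1e-9)
        assert r.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_pure_bias_forgiven(self):
        auto = np.array([100.0, 200.0, 300.0, 420.0])
        r = regression_fit(auto + 28.0, auto)
        assert r.r_squared == pytest.approx(1.0)
        assert r.offset == pytest.approx(28.0, abs=1e-9)
        assert r.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        auto = rng.uniform(200, 1000, 10)
        manual = 0.9 * auto + 30 + rng.normal(0, 20, 10)
        r = regression_fit(manual, auto)
        n = auto.size
        sx, sy = auto.sum(), manual.sum()
        sxx, sxy = (auto**2).sum(), (auto * manual).sum()
        b1 = (n * sxy - sx * sy) / (n * sxx - sx**2)
        b0 = (sy - b1 * sx) / n
        syy = (manual**2).sum()
        r2 = (n * sxy - sx * sy) ** 2 / ((n * sxx - sx**2) * (n * syy - sy**2))
        assert r.slope == pytest.approx(b1, abs=1e-10)
        assert r.offset == pytest.approx(b0, abs=1e-10)
        assert r.r_squared == pytest.approx(r2, abs=1e-10)

    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(1)
        auto = rng.uniform(0, 1000, 50)
        manual = auto + rng.normal(0, 30, 50)
        r = regression_fit(manual, auto)
        assert r.residuals.sum() == pytest.approx(0.0, abs=1e-6)

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateRegressionError):
            regression_fit([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestShiftInvariance:
    def test_shift_moves_ad_but_not_residuals(self):
        """A constant bias changes |AD| proportions but not the regression
        residual measures — the divergence that motivates reporting both."""
        rng = np.random.default_rng(2)
        auto = rng.uniform(300, 900, 100)
        manual = auto + rng.normal(0, 5, 100)
        base = evaluate(manual, auto)
        shifted = evaluate(manual, auto + 30.0)
        # the intercept absorbs the shift scaled by the (near-1) slope
        expect_offset = base.regression.offset - 30.0 * base.regression.slope
        assert shifted.regression.offset == pytest.approx(expect_offset, abs=1e-8)
        assert shifted.regression.r_squared == pytest.approx(base.regression.r_squared, abs=1e-10)
        np.testing.assert_allclose(shifted.regression.residuals, base.regression.residuals, atol=1e-8)
        assert shifted.regression.residual_sd == pytest.approx(base.regression.residual_sd, abs=1e-8)
        # the |AD| proportion collapses under the 30 ms shift
        assert base.ad.prop_within_10ms > 0.9
        assert shifted.ad.prop_within_10ms < 0.1


class TestICC:
    def test_identical_columns_give_one(self):
        m = np.column_stack([np.arange(10.0), np.arange(10.0)])
        assert icc(m).icc == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(3)
        m = rng.normal(0, 1, size=(1000, 2))
        assert abs(icc(m).icc) < 0.1

    def test_matches_hand_computed_anova_oracle(self):
        m = np.array(
            [[9.0, 2.0], [1.0, 10.0], [8.0, 9.0], [2.0, 6.0], [10.0, 6.0], [6.0, 8.0]]
        )
        n, k = m.shape
        grand = m.mean()
        ss_rows = k * sum((m[i].mean() - grand) ** 2 for i in range(n))
        ss_cols = n * sum((m[:, j].mean() - grand) ** 2 for j in range(k))
        ss_err = ((m - grand) ** 2).sum() - ss_rows - ss_cols
        ms_rows = ss_rows / (n - 1)
        ms_err = ss_err / ((n - 1) * (k - 1))
        expect = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
        assert icc(m).icc == pytest.approx(expect, abs=1e-8)

    def test_matches_pingouin_cross_check(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(4)
        truth = rng.uniform(300, 900, 40)
        m = truth[:, None] + rng.normal(0, 25, size=(40, 3)) + np.array([0.0, 10.0, -5.0])
        long = pd.DataFrame(
            {
                "trial": np.repeat(np.arange(40), 3),
                "rater": np.tile(np.arange(3), 40),
                "y": m.ravel(),
            }
        )
        table = pg.intraclass_corr(long, targets="trial", raters="rater", ratings="y")
        expect = float(table.set_index("Type").loc["ICC(C,1)", "ICC"])
        assert icc(m).icc == pytest.approx(expect, abs=1e-8)

    def test_two_rater_consistency_equals_pearson_after_centering(self):
        rng = np.random.default_rng(5)
        truth = rng.uniform(0, 100, 200)
        m = truth[:, None] + rng.normal(0, 10, size=(200, 2))
        centered = m - m.mean(axis=0)
        r = np.corrcoef(centered[:, 0], centered[:, 1])[0, 1]
        assert icc(m).icc == pytest.approx(r, abs=0.01)

    def test_missing_cells_raise(self):
        m = np.column_stack([np.arange(5.0), np.arange(5.0)])
        m[2, 1] = np.nan
        with pytest.raises(IncompleteDesignError):
            icc(m)

    def test_never_exceeds_one(self):
        rng = np.random.default_rng(6)
        for seed in range(20):
            m = rng.normal(0, 1, size=(8, 3))
            assert icc(m).icc <= 1.0 + 1e-12


class TestGroupedReport:
    def test_single_group_equals_ungrouped(self):
        rng = np.random.default_rng(7)
        auto = rng.uniform(200, 800, 30)
        manual = auto + rng.normal(0, 10, 30)
        rep = grouped_report(manual, auto, ["a"] * 30)
        full = evaluate(manual, auto)
        assert rep["a"].regression.r_squared == pytest.approx(full.regression.r_squared)

    def test_groups_partition_the_pairs(self):
        rng = np.random.default_rng(8)
        auto = rng.uniform(200, 800, 40)
        manual = auto + rng.normal(0, 10, 40)
        labels = ["a"] * 25 + ["b"] * 15
        rep = grouped_report(manual, auto, labels)
        assert rep["a"].n_pairs + rep["b"].n_pairs == 40

    def test_small_group_skipped_with_warning(self):
        auto = np.array([100.0, 200.0, 300.0, 400.0, 150.0])
        manual = auto + 5
        with pytest.warns(UserWarning):
            rep = grouped_report(manual, auto, ["a", "a", "a", "a", "b"])
        assert "b" not in rep


def test_residual_sd_consistent_with_optimizer_objective():
    from voiceonset import residual_sd_objective

    rng = np.random.default_rng(9)
    auto = rng.uniform(200, 900, 25)
    manual = auto + rng.normal(0, 15, 25)
    assert regression_fit(manual, auto).residual_sd == pytest.approx(
        residual_sd_objective(auto, manual), rel=1e-12
    )
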