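import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lionwelfare import (
    GroupSummary,
    UndefinedIndexError,
    ValidationError,
    cohens_d,
    cohens_d_rms,
    combine_summaries,
    compare_all,
    correlation_matrix,
    ks_test,
    normality_screen,
    ols_fit,
    pooled_t_test,
    r2_from_correlations,
)


class TestPooledT:
    def test_identical_groups_give_zero(self):
        g = GroupSummary("a", 10, 5.0, 1.0)
        res = pooled_t_test(g, GroupSummary("b", 10, 5.0, 1.0))
        assert res.statistic == 0.0
        assert res.df == 18

    def test_summaries_equal_raw_samples(self, rng):
        """t from (n, mean, sd) summaries matches t from raw data to 1e-12."""
        for _ in range(20):
            a = rng.normal(0, 1, size=rng.integers(4, 30))
            b = rng.normal(0.5, 1.5, size=rng.integers(4, 30))
            from_raw = pooled_t_test(a, b)
            from_sum = pooled_t_test(
                GroupSummary.from_sample("a", a), GroupSummary.from_sample("b", b)
            )
            assert abs(from_raw.statistic - from_sum.statistic) < 1e-12
            assert from_raw.df == from_sum.df

    @pytest.mark.parametrize("equal_var", [True, False])
    def test_matches_scipy(self, rng, equal_var):
        a = rng.normal(0, 1, size=16)
        b = rng.normal(0.7, 1.4, size=19)
        ours = pooled_t_test(a, b, equal_var=equal_var)
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
        assert ours.statistic == pytest.approx(abs(t), abs=1e-12)
        assert ours.p == pytest.approx(p, abs=1e-12)

    def test_textbook_hand_computation(self):
        # pooled t for (1,2,3) vs (4,5,6): diff -3, sp^2 = 1, se = sqrt(2/3)
        res = pooled_t_test(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert res.statistic == pytest.approx(3.0 / np.sqrt(2.0 / 3.0), abs=1e-10)
        assert res.df == 4

    def test_zero_variance_unequal_means_is_error(self):
        with pytest.raises(UndefinedIndexError):
            pooled_t_test(GroupSummary("a", 5, 1.0, 0.0), GroupSummary("b", 5, 2.0, 0.0))

    def test_direction_field(self):
        res = pooled_t_test(
            GroupSummary("low", 10, 1.0, 0.5), GroupSummary("high", 10, 2.0, 0.5)
        )
        assert res.direction == "high"
        assert res.statistic > 0


class TestCohensD:
    def test_identical_groups(self):
        g = GroupSummary("a", 10, 3.0, 1.0)
        assert cohens_d_rms(g, GroupSummary("b", 12, 3.0, 2.0)) == 0.0

    def test_symmetry_and_scale_equivariance(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(1, 2, 15)
        ga, gb = GroupSummary.from_sample("a", a), GroupSummary.from_sample("b", b)
        assert cohens_d_rms(ga, gb) == pytest.approx(cohens_d_rms(gb, ga))
        ga3 = GroupSummary.from_sample("a", 3 * a)
        gb3 = GroupSummary.from_sample("b", 3 * b)
        assert cohens_d_rms(ga, gb) == pytest.approx(cohens_d_rms(ga3, gb3))

    def test_rms_and_pooled_variants_differ_when_ns_differ(self):
        a = GroupSummary("a", 21, 11.13, 3.65)
        b = GroupSummary("b", 14, 102.71, 17.4)
        d_rms = cohens_d(a, b, method="rms")
        d_pooled = cohens_d(a, b, method="pooled")
        assert d_rms == pytest.approx(7.28, abs=0.03)
        assert d_pooled > 8.0  # the pooled-SD variant overshoots this contrast

    def test_both_zero_sds_error(self):
        with pytest.raises(UndefinedIndexError):
            cohens_d(GroupSummary("a", 5, 1.0, 0.0), GroupSummary("b", 5, 1.0, 0.0))


def ks_oracle(a, b):
    """Sup distance between empirical CDFs, scanned over the pooled support."""
    grid = np.concatenate([a, b])
    fa = np.array([(a <= x).mean() for x in grid])
    fb = np.array([(b <= x).mean() for x in grid])
    return float(np.abs(fa - fb).max())


class TestKS:
    def test_identical_samples(self):
        x = np.array([1.0, 2, 3, 4])
        assert ks_test(x, x).ks_d == 0.0

    def test_disjoint_supports(self):
        res = ks_test(np.array([1.0, 2, 3]), np.array([10.0, 11, 12]))
        assert res.ks_d == 1.0

    def test_matches_bruteforce_cdf_oracle(self, rng):
        for _ in range(100):
            a = rng.normal(0, 1, size=rng.integers(5, 40))
            b = rng.normal(rng.uniform(-1, 1), 1.3, size=rng.integers(5, 40))
            res = ks_test(a, b)
            assert res.ks_d == pytest.approx(ks_oracle(a, b), abs=1e-12)
            en = np.sqrt(a.size * b.size / (a.size + b.size))
            assert res.statistic == pytest.approx(res.ks_d * en)

    def test_asymptotic_p_from_z(self, rng):
        a = rng.normal(0, 1, 25)
        b = rng.normal(1.0, 1, 25)
        res = ks_test(a, b)
        assert res.p == pytest.approx(float(sps.kstwobign.sf(res.statistic)))


class TestCombineSummaries:
    def test_matches_pooled_sample(self, rng):
        a = rng.normal(3, 2, 21)
        b = rng.normal(9, 4, 14)
        combined = combine_summaries(
            GroupSummary.from_sample("a", a), GroupSummary.from_sample("b", b)
        )
        pooled = np.concatenate([a, b])
        assert combined.n == 35
        assert combined.mean == pytest.approx(pooled.mean())
        assert combined.sd == pytest.approx(pooled.std(ddof=1))


class TestCorrelations:
    def test_self_correlation_and_symmetry(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        cm = correlation_matrix(df)
        assert np.allclose(np.diag(cm.r), 1.0)
        assert np.allclose(cm.r, cm.r.T)
        assert (cm.r.abs() <= 1 + 1e-12).all().all()

    def test_perfect_anticorrelation(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [4.0, 3, 2, 1], "z": [1.0, 1, 2, 2]})
        cm = correlation_matrix(df)
        assert cm.r.loc["x", "y"] == pytest.approx(-1.0)

    def test_three_point_hand_case(self):
        df = pd.DataFrame({"x": [1.0, 2, 3], "y": [2.0, 4, 7], "z": [0.0, 1, 0]})
        cm = correlation_matrix(df, ("x", "y"))
        # cov = 2.5, sx = 1, sy = sqrt(19/3)
        assert cm.r.loc["x", "y"] == pytest.approx(2.5 / np.sqrt(19.0 / 3.0), abs=1e-12)

    def test_constant_column_flagged_not_zero(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [5.0, 5, 5, 5]})
        with pytest.warns(UserWarning, match="constant"):
            cm = correlation_matrix(df)
        assert "y" in cm.degenerate
        assert np.isnan(cm.r.loc["x", "y"])


class TestR2Identity:
    def test_orthogonal_predictors_additive(self):
        assert r2_from_correlations(0.6, 0.3, 0.0) == pytest.approx(0.36 + 0.09)

    def test_collinear_predictors_error(self):
        with pytest.raises(UndefinedIndexError):
            r2_from_correlations(0.5, 0.5, 1.0)

    def test_equals_ols_r2_on_sample_correlations(self, rng):
        """Identity check: feeding the sample correlations of simulated data
        reproduces the OLS R^2 exactly."""
        n = 200
        z = rng.normal(size=(n, 3))
        x1 = z[:, 0]
        x2 = 0.66 * z[:, 0] + np.sqrt(1 - 0.66**2) * z[:, 1]
        y = -0.8 * x1 - 0.3 * x2 + 0.5 * z[:, 2]
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        fit = ols_fit(df, "y", ("x1", "x2"))
        r_y1 = np.corrcoef(y, x1)[0, 1]
        r_y2 = np.corrcoef(y, x2)[0, 1]
        r_12 = np.corrcoef(x1, x2)[0, 1]
        assert r2_from_correlations(r_y1, r_y2, r_12) == pytest.approx(
            fit.r_squared, abs=1e-12
        )


class TestOLS:
    def test_exact_linear_fit(self):
        df = pd.DataFrame({"x1": [0.0, 1, 2, 3, 4], "x2": [1.0, 0, 1, 0, 1]})
        df["y"] = 2.0 + 3.0 * df["x1"] - df["x2"]
        fit = ols_fit(df, "y", ("x1", "x2"))
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.coefficients.loc["x1", "estimate"] == pytest.approx(3.0)

    def test_single_predictor_r2_is_r_squared(self, rng):
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        df = pd.DataFrame({"x": x, "y": y})
        fit = ols_fit(df, "y", ("x",))
        assert fit.r_squared == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2)
        assert fit.vif == {"x": 1.0}

    def test_collinearity_warning_and_vif(self, rng):
        x = rng.normal(size=40)
        df = pd.DataFrame({"x1": x, "x2": x + rng.normal(0, 0.05, 40)})
        df["y"] = df["x1"] + rng.normal(size=40)
        with pytest.warns(UserWarning, match="VIF"):
            fit = ols_fit(df, "y", ("x1", "x2"))
        assert all(v > 10 for v in fit.vif.values())

    def test_rank_deficient_design_error(self):
        df = pd.DataFrame({"x1": [1.0, 2, 3, 4], "x2": [2.0, 4, 6, 8], "y": [1.0, 2, 3, 4]})
        with pytest.raises(ValidationError, match="rank"):
            ols_fit(df, "y", ("x1", "x2"))

    def test_parameter_recovery_on_structured_table(self, rng):
        """Coefficients recovered within CI on a table drawn to the study's
        regression structure (diversity on stereotypy and zone bias)."""
        n = 35
        spi = rng.normal(0.58, 0.16, n)
        arb = np.clip(rng.normal(11, 6.5, n), 0, None)
        swi = 1.8 - 0.046 * arb - 0.46 * spi + rng.normal(0, 0.12, n)
        df = pd.DataFrame({"swi": swi, "spi": spi, "arb_percent": arb})
        fit = ols_fit(df, "swi", ("spi", "arb_percent"))
        for name, true in (("spi", -0.46), ("arb_percent", -0.046)):
            est = fit.coefficients.loc[name, "estimate"]
            se = fit.coefficients.loc[name, "std_error"]
            assert abs(est - true) < 3 * se
        assert fit.f_df == (2, 32)


class TestNormalityScreen:
    def test_normal_sample_passes(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=500)})
        report = normality_screen(df)
        assert report.loc[report["test"] == "shapiro", "p"].iloc[0] > 0.05

    def test_lognormal_sample_fails(self, rng):
        df = pd.DataFrame({"x": rng.lognormal(0, 1.0, size=500)})
        report = normality_screen(df)
        assert report.loc[report["test"] == "shapiro", "p"].iloc[0] < 0.05

    def test_constant_column_flagged(self):
        report = normality_screen(pd.DataFrame({"x": [1.0] * 10}))
        assert "degenerate" in report["note"].iloc[0]

    def test_levene_rows_per_factor(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=30)})
        factors = pd.DataFrame({"grp": ["a"] * 15 + ["b"] * 15})
        report = normality_screen(df, factors=factors)
        assert (report["test"] == "levene").sum() == 1


class TestCompareAll:
    def test_sixteen_comparisons_on_study_table(self, small_results):
        report = small_results.comparisons
        assert len(report) == 16
        assert set(report["factor"]) == {"personality", "origin", "sex", "social_grouping"}
        assert (report.loc[report["index"] == "latency_s", "test"] == "ks").all()
        assert (report.loc[report["index"] != "latency_s", "test"] == "pooled_t").all()
        assert (report.loc[report["test"] == "pooled_t", "df"] == 33).all()

    def test_small_level_skipped_with_warning(self, rng):
        table = pd.DataFrame(
            {
                "spi": rng.uniform(0, 1, 6),
                "swi": rng.uniform(0, 2, 6),
                "arb_percent": rng.uniform(0, 20, 6),
                "latency_s": rng.uniform(1, 600, 6),
                "personality": ["bold"] * 5 + ["shy"],
            }
        )
        with pytest.warns(UserWarning, match="skipped"):
            report = compare_all(table, factors=("personality",))
        assert (report["test"] == "skipped (n<2)").all()
        assert len(report) == 4

    def test_holm_column_optional(self, small_results):
        table = small_results.analysis_table
        report = compare_all(table, holm=True)
        assert "p_holm" in report.columns
        assert (report["p_holm"].dropna() >= report["p"].dropna() - 1e-15).all()
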