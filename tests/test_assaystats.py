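"""Assay statistics: CV arithmetic, normality tests, gated t-test,
volume↔diameter conversion, lack-of-fit linearity."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from spheromorph.assaystats import (
    StatsError,
    assay_summary,
    cv,
    cv_from_moments,
    diameter_to_volume,
    jarque_bera,
    lilliefors,
    linearity_assessment,
    round_to_nearest,
    t_test_unpaired,
    volume_to_diameter,
)
from spheromorph.assaystats import _lilliefors_stat


class TestCV:
    @pytest.mark.parametrize(
        "mean,sd,expected",
        [(880, 21, 2.4), (347, 87, 25.1), (359, 95, 26.5), (897, 98, 10.9)],
    )
    def test_printed_population_moments(self, mean, sd, expected):
        assert cv_from_moments(mean, sd) == expected

    def test_equal_values_zero(self):
        assert cv([5.0, 5.0, 5.0]) == 0.0

    def test_sample_cv_uses_n_minus_1(self):
        x = [2.0, 4.0, 6.0]
        assert cv(x) == round(100.0 * 2.0 / 4.0, 1)

    def test_zero_mean_undefined(self):
        with pytest.raises(StatsError, match="undefined CV"):
            cv([-1.0, 1.0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        k=st.floats(min_value=1e-3, max_value=1e3),
        seed=st.integers(min_value=0, max_value=100),
    )
    def test_scale_invariance(self, k, seed):
        x = np.random.default_rng(seed).uniform(1.0, 10.0, 12)
        assert cv(k * x) == cv(x)


class TestJarqueBera:
    def test_symmetric_sample_reduces_to_kurtosis_term(self):
        x = np.array([-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0, 0.0])
        res = jarque_bera(x)
        assert res.extras["skewness"] == pytest.approx(0.0, abs=1e-12)
        k = res.extras["kurtosis"]
        assert res.statistic == pytest.approx(len(x) * (k - 3.0) ** 2 / 24.0)

    def test_matches_statsmodels(self):
        from statsmodels.stats.stattools import jarque_bera as sm_jb

        x = np.random.default_rng(1).normal(2.0, 3.0, 150)
        res = jarque_bera(x)
        jb, p, skew, kurt = sm_jb(x)
        assert res.statistic == pytest.approx(jb, rel=1e-12)
        assert res.pvalue == pytest.approx(p, rel=1e-12)

    def test_small_sample_precondition(self):
        with pytest.raises(StatsError):
            jarque_bera([1.0, 2.0, 3.0])

    def test_power_on_exponential(self):
        rng = np.random.default_rng(2)
        rejections = sum(
            jarque_bera(rng.exponential(1.0, 200)).pvalue < 0.05 for _ in range(200)
        )
        assert rejections / 200 >= 0.95

    def test_degenerate_sample(self):
        with pytest.raises(StatsError, match="degenerate"):
            jarque_bera(np.full(20, 3.0))


class TestLilliefors:
    def test_statistic_matches_statsmodels(self):
        from statsmodels.stats.diagnostic import lilliefors as sm_lf

        x = np.random.default_rng(3).normal(5.0, 2.0, 80)
        assert _lilliefors_stat(x) == pytest.approx(sm_lf(x)[0], rel=1e-10)

    def test_uniform_rejected_in_most_seeded_reps(self):
        # power of the Lilliefors test against U(0,1) reaches ~0.95 at
        # n = 200 (at n = 100 it is only ~0.54, for statsmodels' reference
        # implementation as well)
        rng = np.random.default_rng(4)
        rejections = sum(
            lilliefors(rng.uniform(0, 1, 200), mc_reps=400, seed=s).pvalue < 0.05
            for s in range(20)
        )
        assert rejections >= 18  # >= 90%

    def test_small_sample_precondition(self):
        with pytest.raises(StatsError):
            lilliefors([1.0, 2.0, 3.0, 4.0])

    def test_normal_sample_not_rejected(self):
        x = np.random.default_rng(5).standard_normal(60)
        assert lilliefors(x, mc_reps=500, seed=0).pvalue > 0.05


class TestTTest:
    def test_identical_groups(self):
        res = t_test_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], check_normality=False)
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_textbook_pooled_t(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [2.0, 3.0, 4.0, 5.0, 6.0]
        res = t_test_unpaired(a, b, check_normality=False)
        # hand computation: means 3, 4; pooled var 2.5; t = -1/sqrt(2.5*2/5)
        assert res.statistic == pytest.approx(-1.0, abs=1e-12)
        t_sp, p_sp = stats.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(t_sp, rel=1e-12)
        assert res.pvalue == pytest.approx(p_sp, rel=1e-12)

    def test_welch_option(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 3, 12)
        res = t_test_unpaired(a, b, check_normality=False, welch=True)
        t_w, p_w = stats.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(t_w, rel=1e-12)
        assert res.pvalue == pytest.approx(p_w, rel=1e-12)

    def test_gate_refuses_skewed_groups(self):
        rng = np.random.default_rng(7)
        a = rng.exponential(1.0, 60)
        b = rng.exponential(1.5, 60)
        with pytest.raises(StatsError, match="normality gate"):
            t_test_unpaired(a, b)
        res = t_test_unpaired(a, b, check_normality=False)
        assert np.isfinite(res.statistic)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 15), rng.normal(1, 1, 18)
        r1 = t_test_unpaired(a, b, check_normality=False)
        r2 = t_test_unpaired(b, a, check_normality=False)
        assert r1.statistic == pytest.approx(-r2.statistic, rel=1e-12)
        assert r1.pvalue == pytest.approx(r2.pvalue, rel=1e-12)

    def test_zero_variance_cases(self):
        res = t_test_unpaired([2.0, 2.0], [2.0, 2.0], check_normality=False)
        assert res.pvalue == 1.0
        with pytest.raises(StatsError, match="degenerate variance"):
            t_test_unpaired([2.0, 2.0], [3.0, 3.0], check_normality=False)


class TestVolumeDiameter:
    def test_exact_100um(self):
        assert volume_to_diameter(math.pi / 6.0 * 1e-3) == pytest.approx(100.0, rel=1e-12)

    @pytest.mark.parametrize(
        "v,d_exact,d_rounded",
        [(0.025, 362.8, 350), (0.050, 457.1, 450), (0.100, 575.9, 600),
         (0.150, 659.2, 650), (0.300, 830.6, 850)],
    )
    def test_volumetric_categories(self, v, d_exact, d_rounded):
        d = volume_to_diameter(v)
        assert d == pytest.approx(d_exact, abs=0.5)
        assert round_to_nearest(d, 50.0) == d_rounded

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(v=st.floats(min_value=1e-6, max_value=10.0))
    def test_round_trip(self, v):
        assert diameter_to_volume(volume_to_diameter(v)) == pytest.approx(v, rel=1e-10)

    def test_nonpositive_rejected(self):
        with pytest.raises(StatsError):
            volume_to_diameter(0.0)
        with pytest.raises(StatsError):
            diameter_to_volume(-1.0)


class TestLinearity:
    @staticmethod
    def design(rng=None, signal=lambda v: 10 + 100 * v, noise=0.0):
        cats = np.repeat([0.025, 0.05, 0.10, 0.15, 0.30], 9)
        y = signal(cats)
        if noise and rng is not None:
            y = y + rng.normal(0, noise, cats.size)
        return pd.DataFrame({"category": cats, "value": y})

    def test_collinear_means_zero_lack_of_fit(self):
        res = linearity_assessment(self.design())
        assert res.ss_lack_of_fit == pytest.approx(0.0, abs=1e-18)
        assert res.pvalue == 1.0

    def test_slope_and_intercept_recovered(self):
        res = linearity_assessment(self.design())
        assert res.slope == pytest.approx(100.0)
        assert res.intercept == pytest.approx(10.0)

    def test_affine_invariance_of_f(self):
        rng = np.random.default_rng(9)
        df = self.design(rng, noise=1.0)
        res = linearity_assessment(df)
        df2 = df.assign(value=3.5 * df["value"] - 7.0)
        res2 = linearity_assessment(df2)
        assert res2.f_statistic == pytest.approx(res.f_statistic, rel=1e-9)
        assert res2.pvalue == pytest.approx(res.pvalue, rel=1e-9)

    def test_plateau_alternative_detected(self):
        rng = np.random.default_rng(10)
        df = self.design(rng, signal=lambda v: 10 + 100 * np.minimum(v, 0.15), noise=1.0)
        assert linearity_assessment(df).pvalue < 0.05

    def test_preconditions(self):
        df = pd.DataFrame({"category": [1, 1, 2, 2], "value": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(StatsError, match="3 categories"):
            linearity_assessment(df)
        df = pd.DataFrame({"category": [1, 1, 2, 2, 3], "value": [1, 2, 3, 4, 5.0]})
        with pytest.raises(StatsError, match="pure-error"):
            linearity_assessment(df)


class TestAssaySummary:
    def test_single_condition(self):
        df = pd.DataFrame({"condition": ["CTR"] * 4, "value": [7.0, 7.0, 7.0, 7.0]})
        out, avg_cv = assay_summary(df)
        assert out.loc["CTR", "cv_percent"] == 0.0
        assert out.loc["CTR", "percent_of_control"] == 100.0

    def test_hand_computed_moments(self):
        df = pd.DataFrame(
            {
                "condition": ["CTR"] * 3 + ["dose1"] * 3,
                "value": [10.0, 12.0, 14.0, 5.0, 6.0, 7.0],
            }
        )
        out, avg_cv = assay_summary(df)
        assert out.loc["CTR", "mean"] == 12.0
        assert out.loc["CTR", "sd"] == pytest.approx(2.0)
        assert out.loc["dose1", "percent_of_control"] == pytest.approx(50.0)
        assert avg_cv == pytest.approx(
            (round(100 * 2 / 12, 1) + round(100 * 1 / 6, 1)) / 2.0
        )

    def test_average_cv_unweighted(self):
        rows = []
        for label, m, s in (("a", 100.0, 10.0), ("b", 100.0, 20.0), ("c", 100.0, 30.0)):
            rows += [
                {"condition": label, "value": m - s},
                {"condition": label, "value": m + s},
            ]
        df = pd.DataFrame(rows)
        _, avg_cv = assay_summary(df, control=None)
        # two-point samples: sd = s*sqrt(2), so cvs are 14.1, 28.3, 42.4
        assert avg_cv == pytest.approx((14.1 + 28.3 + 42.4) / 3.0, abs=0.05)

    def test_missing_control_warns(self):
        df = pd.DataFrame({"condition": ["x"] * 2, "value": [1.0, 2.0]})
        with pytest.warns(UserWarning, match="control"):
            out, _ = assay_summary(df, control="CTR")
        assert "percent_of_control" not in out.columns
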