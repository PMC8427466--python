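"""Statistical layer: agreement, CoV equality, group tests, mixed ANOVA."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from hepaflow.stats import (GroupSummary, attrition_inflate, bland_altman,
                            coefficient_of_variation, forkman_cov_test,
                            forkman_from_samples, ks_normality,
                            mann_whitney_u, mixed_anova_2x2, welch_t)


class TestBlandAltman:
    def test_identical_pairs(self):
        r = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.bias == 0.0 and r.loa_low == 0.0 and r.loa_high == 0.0

    def test_hand_computed_case(self):
        b = np.zeros(3)
        r = bland_altman(b + np.array([-50.0, -10.0, 10.0]), b)
        assert r.bias == pytest.approx(-16.667, abs=1e-3)
        assert r.sd_diff == pytest.approx(30.551, abs=1e-3)
        assert r.loa_low == pytest.approx(-76.546, abs=1e-2)
        assert r.loa_high == pytest.approx(43.212, abs=1e-2)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 25), rng.normal(0, 1, 25)
        r = bland_altman(a, b)
        d = a - b
        assert r.bias == d.mean()
        assert r.sd_diff == d.std(ddof=1)
        assert r.loa_high == r.bias + 1.96 * r.sd_diff

    def test_pairs_array_input_and_small_n(self):
        r = bland_altman(np.array([[1.0, 0.0], [2.0, 1.0], [3.0, 1.0]]))
        assert r.n == 3
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [0.0, 0.0])


class TestCov:
    def test_constant_sample_zero(self):
        assert coefficient_of_variation([5.0, 5.0, 5.0]) == 0.0

    def test_known_value(self):
        assert coefficient_of_variation([1.0, 2.0, 3.0]) == pytest.approx(50.0)

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, k):
        x = np.array([3.0, 5.0, 9.0, 11.0])
        assert coefficient_of_variation(k * x) == pytest.approx(
            coefficient_of_variation(x), rel=1e-9)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, 1.0])


class TestForkman:
    def test_equal_covs_give_unit_f(self):
        r = forkman_cov_test(0.3, 10, 0.3, 10)
        assert r.F == pytest.approx(1.0)
        assert r.p_two_sided == pytest.approx(1.0)

    def test_reported_cov_comparison_case(self):
        # CoVs 29.3% vs 50.1% with 19 subjects per method
        r = forkman_cov_test(0.293, 19, 0.501, 19)
        assert round(r.F, 2) == 0.39
        assert (r.df1, r.df2) == (18, 18)

    def test_reciprocity_under_sample_swap(self):
        a = forkman_cov_test(0.293, 19, 0.501, 19)
        b = forkman_cov_test(0.501, 19, 0.293, 19)
        assert a.F == pytest.approx(1.0 / b.F)
        assert a.p_two_sided == pytest.approx(b.p_two_sided)

    def test_from_samples_consistent(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(50, 5, 12), rng.normal(80, 20, 15)
        r = forkman_from_samples(x, y)
        assert r.cov1_pct == pytest.approx(coefficient_of_variation(x))
        assert (r.df1, r.df2) == (11, 14)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            forkman_cov_test(-0.1, 10, 0.2, 10)
        with pytest.raises(ValueError):
            forkman_cov_test(0.1, 1, 0.2, 10)


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_reported_group_summaries(self):
        # liver T1 group summaries: (1256 +/- 18, n=10) vs (1533 +/- 50, n=9)
        t, df, p = welch_t(GroupSummary(1256.0, 18.0, 10),
                           GroupSummary(1533.0, 50.0, 9))
        assert abs(t) == pytest.approx(5.213, abs=2e-3)
        assert df == pytest.approx(10.06, abs=0.01)
        assert p < 0.001

    def test_sample_and_summary_paths_agree(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 2, 9)
        direct = welch_t(x, y)
        via_summary = welch_t(
            GroupSummary(x.mean(), x.std(ddof=1) / np.sqrt(len(x)), len(x)),
            GroupSummary(y.mean(), y.std(ddof=1) / np.sqrt(len(y)), len(y)))
        assert direct == pytest.approx(via_summary, rel=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, 15), rng.normal(1, 3, 8)
        t, df, p = welch_t(x, y)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_double_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_t(GroupSummary(1.0, 0.0, 5), GroupSummary(2.0, 0.0, 5))


class TestMannWhitney:
    def test_fully_separated_samples_exact_p(self):
        u, p = mann_whitney_u([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 extreme labellings / C(6,3)

    def test_identical_samples(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p == pytest.approx(1.0)

    def test_exact_matches_permutation_enumeration(self):
        rng = np.random.default_rng(11)
        pooled = rng.normal(0, 1, 8)
        x_obs, y_obs = pooled[:4], pooled[4:]
        u_obs, p_obs = mann_whitney_u(x_obs, y_obs)

        def u_stat(x, y):
            return sum((xi > yi) + 0.5 * (xi == yi)
                       for xi in x for yi in y)

        us = [u_stat(pooled[list(idx)],
                     pooled[[i for i in range(8) if i not in idx]])
              for idx in itertools.combinations(range(8), 4)]
        us = np.array(us)
        p_perm = min(1.0, 2.0 * min(float(np.mean(us <= u_obs)),
                                    float(np.mean(us >= u_obs))))
        assert p_obs == pytest.approx(p_perm, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestKsNormality:
    def test_statistic_matches_brute_force(self):
        rng = np.random.default_rng(1)
        x = rng.normal(10, 2, 23)
        D, _ = ks_normality(x)
        z = np.sort((x - x.mean()) / x.std(ddof=1))
        cdf = sps.norm.cdf(z)
        n = len(z)
        brute = max(max(abs((i + 1) / n - cdf[i]), abs(cdf[i] - i / n))
                    for i in range(n))
        assert D == pytest.approx(brute, abs=1e-12)

    def test_statistic_matches_statsmodels_lilliefors(self):
        from statsmodels.stats.diagnostic import lilliefors

        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 30)
        D, p = ks_normality(x, seed=0)
        D_ref, p_ref = lilliefors(x, dist="norm", pvalmethod="table")
        assert D == pytest.approx(D_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=0.05)

    def test_exact_normal_quantiles_minimise_d(self):
        n = 20
        x = sps.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        D, p = ks_normality(x)
        assert D < 0.06
        assert p > 0.9

    def test_power_against_skewed_alternative(self):
        rng = np.random.default_rng(42)
        rejections = sum(
            ks_normality(rng.exponential(1.0, 50), seed=100 + i)[1] < 0.05
            for i in range(40))
        assert rejections >= 38  # >= 95% of replicates

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0, 3.0])


class TestMixedAnova:
    @staticmethod
    def _records(changes_a, changes_b, base=100.0):
        rows = []
        for g, changes in (("A", changes_a), ("B", changes_b)):
            for i, d in enumerate(changes):
                rows.append((f"{g}{i}", g, "t0_baseline", base))
                rows.append((f"{g}{i}", g, "t1_post", base + d))
        return pd.DataFrame(rows, columns=["subject", "group", "time", "value"])

    def test_parallel_changes_give_zero_interaction(self):
        r = mixed_anova_2x2(self._records([5.0, 7.0], [5.0, 7.0]))
        assert r.f_interaction == pytest.approx(0.0, abs=1e-20)

    def test_hand_computed_interaction(self):
        # change scores {10, 14} vs {0, 2}: t = 11/sqrt(5), F = 24.2, df (1, 2)
        r = mixed_anova_2x2(self._records([10.0, 14.0], [0.0, 2.0]))
        assert r.f_interaction == pytest.approx(24.2, rel=1e-9)
        assert (r.df1, r.df2) == (1, 2)

    def test_subject_constant_invariance(self):
        df = self._records([3.0, 9.0, 6.0], [1.0, -2.0, 0.0])
        r1 = mixed_anova_2x2(df)
        shifted = df.copy()
        offsets = {s: 10.0 * k for k, s in enumerate(shifted["subject"].unique())}
        shifted["value"] += shifted["subject"].map(offsets)
        r2 = mixed_anova_2x2(shifted)
        assert r2.f_interaction == pytest.approx(r1.f_interaction, rel=1e-9)

    def test_matches_pingouin_oracle(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        rows = []
        for g, n in (("A", 6), ("B", 5)):
            for i in range(n):
                for t in ("t0", "t1"):
                    val = rng.normal(10 if (t == "t1" and g == "A") else 0, 3)
                    rows.append((f"{g}{i}", g, t, float(val)))
        df = pd.DataFrame(rows, columns=["subject", "group", "time", "value"])
        mine = mixed_anova_2x2(df)
        aov = pg.mixed_anova(data=df, dv="value", within="time",
                             subject="subject", between="group")
        ref = aov[aov["Source"] == "Interaction"].iloc[0]
        assert mine.f_interaction == pytest.approx(float(ref["F"]), rel=1e-9)
        assert mine.df2 == int(ref["DF2"])
        assert mine.p_interaction == pytest.approx(float(ref["p_unc"]), rel=1e-9)

    def test_incomplete_subject_dropped_with_warning(self):
        df = self._records([3.0, 9.0, 6.0], [1.0, -2.0, 0.0])
        df = df[~((df["subject"] == "B2") & (df["time"] == "t1_post"))]
        with pytest.warns(UserWarning, match="B2"):
            r = mixed_anova_2x2(df)
        assert r.dropped_subjects == ("B2",)
        assert r.df2 == 3  # 5 complete subjects - 2

    def test_posthoc_bonferroni_doubles_p(self):
        r = mixed_anova_2x2(self._records([3.0, 9.0, 6.0], [1.0, -2.0, 0.0]))
        for g in ("A", "B"):
            t, df, p_raw, p_adj = r.posthoc[g]
            assert p_adj == pytest.approx(min(1.0, 2 * p_raw))


class TestAttrition:
    @pytest.mark.parametrize("n, rate, expected", [
        (6, 0.30, 9),   # the study's planning computation
        (6, 0.0, 6),
        (10, 0.5, 20),
    ])
    def test_inflation(self, n, rate, expected):
        assert attrition_inflate(n, rate) == expected

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            attrition_inflate(6, 1.0)
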