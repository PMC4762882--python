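"""Permutation ANOVA, contrasts, rates, Kruskal-Wallis and power."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from mutburden.stats import (
    anova_F,
    anova_power,
    cadd_comparison,
    contrast_test,
    enumerate_partitions,
    filter_reportable,
    kruskal_wallis_scores,
    n_partitions,
    permutation_anova,
    relative_rates,
    sample_size_for_power,
)


def brute_force_partitions(ids, sizes):
    """Independent oracle: every ordered choice of groups, deduplicated as a
    set of frozensets."""
    def rec(remaining, sizes):
        if not sizes:
            yield frozenset()
            return
        for combo in itertools.combinations(sorted(remaining), sizes[0]):
            rest = set(remaining) - set(combo)
            for sub in rec(rest, sizes[1:]):
                yield frozenset({frozenset(combo)}) | sub
    return set(rec(set(ids), list(sizes)))


class TestEnumeratePartitions:
    @pytest.mark.parametrize(
        "n,sizes,expected",
        [
            (9, (3, 3, 3), 280),   # the full study design
            (4, (2, 2), 3),
            (3, (1, 1, 1), 1),
            (5, (2, 3), 10),
            (4, (1, 1, 2), 6),
        ],
    )
    def test_counts(self, n, sizes, expected):
        parts = enumerate_partitions(range(n), sizes)
        assert len(parts) == expected
        assert n_partitions(sizes) == expected

    @pytest.mark.parametrize("n,sizes", [(9, (3, 3, 3)), (6, (2, 2, 2)),
                                         (5, (2, 3)), (10, (2, 2, 3, 3))])
    def test_matches_brute_force(self, n, sizes):
        parts = enumerate_partitions(range(n), sizes)
        as_sets = {frozenset(frozenset(g) for g in p) for p in parts}
        assert len(as_sets) == len(parts), "no duplicate partitions"
        assert as_sets == brute_force_partitions(range(n), sizes)

    def test_includes_observed_partition(self):
        parts = enumerate_partitions("abcdefghi", (3, 3, 3))
        observed = frozenset({frozenset("abc"), frozenset("def"), frozenset("ghi")})
        assert observed in {frozenset(frozenset(g) for g in p) for p in parts}

    def test_size_mismatch_raises(self):
        with pytest.raises(ValueError):
            enumerate_partitions(range(5), (3, 3))


class TestAnovaF:
    def test_worked_example(self, ezh2_counts):
        # SSB = 110.222 (df 2), SSW = 52.667 (df 6)
        assert anova_F(ezh2_counts) == pytest.approx(6.278481012658227, rel=1e-12)

    def test_matches_scipy(self, ezh2_counts, coding_counts):
        for groups in (ezh2_counts, coding_counts):
            expected = sps.f_oneway(*groups).statistic
            assert anova_F(groups) == pytest.approx(expected, rel=1e-12)

    def test_equal_values_give_zero(self):
        assert anova_F([[4, 4, 4], [4, 4, 4], [4, 4, 4]]) == 0.0

    def test_zero_within_variance_gives_inf(self):
        assert math.isinf(anova_F([[1, 1, 1], [2, 2, 2], [3, 3, 3]]))

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            anova_F([[1, 2], []])


class TestPermutationAnova:
    labels = ["m"] * 3 + ["r"] * 3 + ["s"] * 3

    def test_constant_values_give_p_one(self):
        res = permutation_anova([5.0] * 9, self.labels)
        assert res.p_value == 1.0
        assert res.n_partitions == 280

    def test_maximal_separation_gives_minimum_p(self):
        # groups (0,0,0), (10,10,10), (20,20,20): within-variance 0 for the
        # observed labelling only, so F_obs = inf is the strict maximum
        values = [0, 0, 0, 10, 10, 10, 20, 20, 20]
        res = permutation_anova(values, self.labels)
        assert res.p_value == pytest.approx(1 / 280)

    def test_p_is_multiple_of_partition_fraction(self, ezh2_counts):
        values = np.concatenate(ezh2_counts)
        res = permutation_anova(values, self.labels)
        k = round(res.p_value * res.n_partitions)
        assert res.p_value == pytest.approx(k / res.n_partitions, abs=1e-12)
        assert res.p_value >= 1 / res.n_partitions

    def test_matches_loop_recomputation(self, ezh2_counts):
        values = np.concatenate(ezh2_counts)
        res = permutation_anova(values, self.labels, category="EZH2")
        null = [
            anova_F([values[list(g)] for g in part])
            for part in enumerate_partitions(range(9), (3, 3, 3))
        ]
        assert np.allclose(sorted(null), sorted(res.null_F))
        assert res.p_value == np.mean(np.array(null) >= res.F_obs - 1e-12)

    def test_order_invariance(self, ezh2_counts):
        values = np.concatenate(ezh2_counts)
        res1 = permutation_anova(values, self.labels)
        order = np.argsort(values, kind="stable")[::-1]
        res2 = permutation_anova(values[order], np.array(self.labels)[order])
        assert res1.p_value == pytest.approx(res2.p_value)


class TestContrast:
    def test_worked_example(self, ezh2_counts):
        res = contrast_test(ezh2_counts, (-2, 1, 1))
        assert res.estimate == pytest.approx(-44 / 3, rel=1e-12)
        assert res.se == pytest.approx(math.sqrt((79 / 9) * 2), rel=1e-12)
        assert res.t == pytest.approx(-3.500452050373213, rel=1e-12)
        assert res.df == 6
        assert res.p_parametric == pytest.approx(0.012819, abs=1e-5)

    def test_matches_statsmodels_oracle(self, ezh2_counts, coding_counts):
        import statsmodels.api as sm
        for groups in (ezh2_counts, coding_counts):
            y = np.concatenate(groups)
            X = np.zeros((9, 3))
            for i in range(3):
                X[3 * i:3 * i + 3, i] = 1.0
            fit = sm.OLS(y, X).fit()
            for c in [(-2, 1, 1), (1, -2, 1), (1, 1, -2)]:
                oracle = fit.t_test(np.array(c, dtype=float))
                res = contrast_test(groups, c)
                assert res.estimate == pytest.approx(float(oracle.effect[0]), rel=1e-9)
                assert res.se == pytest.approx(float(oracle.sd[0][0]), rel=1e-9)
                assert res.t == pytest.approx(float(oracle.tvalue[0][0]), rel=1e-9)
                assert res.p_parametric == pytest.approx(float(oracle.pvalue), rel=1e-9)

    def test_equal_means_give_zero(self):
        res = contrast_test([[1, 2, 3], [3, 2, 1], [2, 2, 2]], (-2, 1, 1))
        assert res.estimate == 0.0
        assert res.t == 0.0
        assert res.p_parametric == pytest.approx(1.0)

    def test_sign_flip_antisymmetry(self, ezh2_counts):
        plus = contrast_test(ezh2_counts, (-2, 1, 1))
        minus = contrast_test(ezh2_counts, (2, -1, -1))
        assert minus.estimate == pytest.approx(-plus.estimate)
        assert abs(minus.t) == pytest.approx(abs(plus.t))
        assert minus.p_parametric == pytest.approx(plus.p_parametric)
        assert minus.p_permutation == pytest.approx(plus.p_permutation)

    def test_permutation_p_enumerates_84_splits(self, ezh2_counts):
        res = contrast_test(ezh2_counts, (-2, 1, 1))
        assert res.p_permutation is not None
        k = round(res.p_permutation * 84)
        assert res.p_permutation == pytest.approx(k / 84, abs=1e-12)
        assert res.p_permutation >= 1 / 84

    def test_non_zero_sum_contrast_raises(self, ezh2_counts):
        with pytest.raises(ValueError):
            contrast_test(ezh2_counts, (1, 1, 1))


class TestRatesAndFilters:
    def test_relative_rates(self):
        counts = pd.DataFrame({"coding": [2, 5], "igr": [10, 0]},
                              index=["A", "B"])
        totals = pd.Series([10, 5], index=["A", "B"])
        rates = relative_rates(counts, totals)
        assert rates.loc["A", "coding"] == pytest.approx(0.2)
        assert rates.loc["B", "coding"] == pytest.approx(1.0)
        brute = counts.to_numpy() / totals.to_numpy()[:, None]
        assert np.allclose(rates.to_numpy(), brute)

    def test_zero_total_raises(self):
        counts = pd.DataFrame({"coding": [1]}, index=["A"])
        with pytest.raises(ValueError, match="zero total"):
            relative_rates(counts, pd.Series([0], index=["A"]))

    def test_min_variant_reporting_boundary(self):
        counts = pd.DataFrame({"nine": [3, 3, 3], "ten": [4, 3, 3],
                               "many": [20, 0, 0]})
        assert filter_reportable(counts, 10) == ["ten", "many"]
        assert filter_reportable(pd.DataFrame(columns=["a"]), 10) == []


class TestKruskalWallis:
    def test_no_tie_worked_example(self):
        H, p = kruskal_wallis_scores([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert H == pytest.approx(7.2)

    def test_identical_values_give_zero(self):
        H, p = kruskal_wallis_scores([[2, 2], [2, 2, 2]])
        assert H == 0.0 and p == 1.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-50, 50), min_size=3, max_size=8, unique=True))
    def test_monotone_transform_invariance(self, pool):
        groups = [pool[: len(pool) // 2 + 1], pool[len(pool) // 2:]]
        H1, _ = kruskal_wallis_scores(groups)
        H2, _ = kruskal_wallis_scores([[x**3 + 2 * x for x in g] for g in groups])
        assert H1 == pytest.approx(H2, abs=1e-9)

    def test_pooled_and_replicate_modes(self):
        rng = np.random.default_rng(3)
        scores = {f"{m}{i}": rng.normal(loc, 1, 30).tolist()
                  for m, loc in (("M", 0.0), ("R", 2.0), ("S", 2.0))
                  for i in (1, 2, 3)}
        method_of = {s: s[0] for s in scores}
        pooled = cadd_comparison(scores, method_of, mode="pooled")
        assert set(pooled["comparison"]) == {"M vs R", "M vs S", "R vs S"}
        mr = pooled.set_index("comparison").loc["M vs R", "p"]
        rs = pooled.set_index("comparison").loc["R vs S", "p"]
        assert mr < 1e-6 < rs
        reps = cadd_comparison(scores, method_of, mode="replicates")
        assert len(reps) == 3


class TestPower:
    def test_zero_between_variance_is_undefined(self):
        est = sample_size_for_power([[5, 6, 7], [6, 5, 7], [7, 6, 5]])
        assert est.between_var == 0.0
        assert est.n_per_group is None

    def test_coding_counts_worked_example(self, coding_counts):
        est = sample_size_for_power(coding_counts)
        assert est.between_var == pytest.approx(35.111111, rel=1e-6)
        assert est.within_var == pytest.approx(36.888889, rel=1e-6)
        # power crosses 0.80 between n=4 (0.721) and n=5 (0.852)
        assert anova_power(4, 3, est.between_var, est.within_var) < 0.80
        assert anova_power(5, 3, est.between_var, est.within_var) >= 0.80
        assert est.n_per_group == 5

    def test_monotone_in_n(self, coding_counts):
        est = sample_size_for_power(coding_counts)
        powers = [anova_power(n, 3, est.between_var, est.within_var)
                  for n in range(2, 12)]
        assert all(b > a for a, b in zip(powers, powers[1:]))

    def test_large_effect_needs_two_vs_monte_carlo(self):
        # between/within ratio 10: two samples per group suffice, confirmed
        # by simulating the ANOVA rejection rate at n=2
        between, within = 10.0, 1.0
        assert anova_power(2, 3, between, within) >= 0.80
        means = np.array([-1, 0, 1]) * math.sqrt(between)  # var(means, ddof=1) = between
        assert np.var(means, ddof=1) == pytest.approx(between)
        rng = np.random.default_rng(12345)
        n_sim, n = 20_000, 2
        data = rng.normal(means[None, :, None], math.sqrt(within), (n_sim, 3, n))
        gm = data.mean(axis=2)
        grand = data.mean(axis=(1, 2))
        ssb = n * ((gm - grand[:, None]) ** 2).sum(axis=1)
        ssw = ((data - gm[:, :, None]) ** 2).sum(axis=(1, 2))
        F = (ssb / 2) / (ssw / (3 * (n - 1)))
        rate = np.mean(F > sps.f.isf(0.05, 2, 3 * (n - 1)))
        se = math.sqrt(rate * (1 - rate) / n_sim)
        assert rate - 3 * se >= 0.80
        # group values constructed to have exactly between=10, within=1
        a, d = math.sqrt(between), math.sqrt(within / 2)
        values = [[-a - d, -a + d], [-d, d], [a - d, a + d]]
        est = sample_size_for_power(values)
        assert est.between_var == pytest.approx(between)
        assert est.within_var == pytest.approx(within)
        assert est.n_per_group == 2
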