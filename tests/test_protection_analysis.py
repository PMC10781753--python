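"""Protection/urban labels and the rank-based group comparisons."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps
from shapely.geometry import box

from coastsqueeze import (
    assign_protection,
    assign_protection_all,
    assign_urban,
    generate_null_groups,
    kruskal_wallis_posthoc,
    label_groups,
    rank_sum_test,
)
from conftest import make_transect


class TestLabels:
    def test_polygon_in_window_is_protected(self):
        t = make_transect((0, 0), (0, 1))
        assert assign_protection(t, [box(-100, 0, 100, 500.0)])

    def test_polygon_beyond_window_is_not(self):
        t = make_transect((0, 0), (0, 1))
        assert not assign_protection(t, [box(-100, 2500.0, 100, 3000.0)])

    def test_polygon_touching_window_end_counts(self):
        # closed-interval convention: edge exactly at 2,000 m touches
        t = make_transect((0, 0), (0, 1))
        assert assign_protection(t, [box(-100, 2000.0, 100, 2500.0)])

    def test_urban_threshold_boundary(self):
        assert assign_urban(300.0) is True
        assert assign_urban(299.0) is False
        assert assign_urban(0.0) is False
        assert assign_urban(float("nan")) is None

    def test_missing_urban_label_dropped_from_groups(self):
        labels = label_groups(
            np.array([True, False, True]),
            [True, None, False],
            np.array([0, 1, 2]),
        )
        assert list(labels["transect_id"]) == [0, 2]
        assert list(labels["group"]) == ["urban_protected", "rural_protected"]

    def test_world_protection_truth(self, small_world):
        got = assign_protection_all(small_world.transects, small_world.protected_areas)
        np.testing.assert_array_equal(got, small_world.truth["protected"].to_numpy())


def permutation_oracle_ranksum(a, b):
    """Exhaustive two-sided permutation p-value for the rank-sum statistic."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n1, N = len(a), len(pooled)
    mean = n1 * (N + 1) / 2.0
    obs = abs(ranks[:n1].sum() - mean)
    hits = total = 0
    for idx in combinations(range(N), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mean) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestRankSum:
    def test_extreme_separation_exact_p(self):
        # {1,2,3} vs {4,5,6}: rank-sum 6 is maximally extreme;
        # 2 of C(6,3)=20 assignments are as extreme → p = 0.1
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)

    def test_identical_samples_degenerate(self):
        res = rank_sum_test([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(12))
    def test_exact_p_equals_permutation_oracle(self, seed):
        """All small two-group splits agree with exhaustive enumeration."""
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(2, 5))
        n2 = int(rng.integers(2, 9 - n1))
        a = rng.choice(np.arange(1.0, 7.0), size=n1)  # ties possible
        b = rng.choice(np.arange(1.0, 7.0), size=n2)
        if np.all(np.concatenate([a, b]) == a[0]):
            b = b + 1.0
        res = rank_sum_test(a, b, method="exact")
        assert res.p_value == pytest.approx(permutation_oracle_ranksum(a, b))

    def test_asymptotic_z_matches_scipy_u_statistic(self):
        """Z² from the normal approximation equals the (tie-corrected)
        standardised Mann-Whitney U from scipy, without continuity."""
        rng = np.random.default_rng(3)
        a = rng.lognormal(6, 1, 60)
        b = rng.lognormal(6.4, 1, 80)
        res = rank_sum_test(a, b, method="asymptotic", continuity=False)
        u = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                             use_continuity=False)
        # recover z from scipy's p-value
        z_scipy = sps.norm.isf(u.pvalue / 2)
        assert abs(res.statistic) == pytest.approx(z_scipy, rel=1e-9)

    def test_statistic_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        a = rng.lognormal(6, 1, 40)
        b = rng.lognormal(6.5, 1, 50)
        r1 = rank_sum_test(a, b, method="asymptotic")
        r2 = rank_sum_test(np.log(a), np.log(b), method="asymptotic")
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_minimum_sample_size_enforced(self):
        with pytest.raises(ValueError):
            rank_sum_test([1.0], [2.0, 3.0])

    def test_null_type_one_error(self):
        """Rejection rate at α=0.05 stays within binomial 95% bounds over
        1,000 null replicates (both samples from one distribution)."""
        n_rep, alpha = 1000, 0.05
        rejections = 0
        for i in range(n_rep):
            a, b = generate_null_groups(100, seed=10_000 + i)
            res = rank_sum_test(a, b, method="asymptotic")
            rejections += res.p_value < alpha
        rate = rejections / n_rep
        half = 1.96 * math.sqrt(alpha * (1 - alpha) / n_rep)
        assert alpha - half <= rate <= alpha + half


def kw_statistic(groups):
    """Tie-corrected Kruskal-Wallis H for the permutation oracle."""
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    N = len(pooled)
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        start += len(g)
        h += r.sum() ** 2 / len(g)
    h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - ((counts**3 - counts).sum()) / (N**3 - N)
    return h / tie if tie > 0 else 0.0


class TestKruskalWallis:
    def test_identical_groups_zero_statistic(self):
        g = [np.full(5, 7.0)] * 4
        res = kruskal_wallis_posthoc(g)
        assert res.statistic == 0.0 and res.p_value == 1.0
        assert res.df == 3
        assert not res.posthoc["significant"].any()

    def test_df_is_groups_minus_one(self):
        rng = np.random.default_rng(5)
        res = kruskal_wallis_posthoc([rng.normal(size=6) for _ in range(4)])
        assert res.df == 3
        res2 = kruskal_wallis_posthoc([rng.normal(size=6) for _ in range(3)])
        assert res2.df == 2

    def test_small_group_dropped_with_reduced_df(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(size=8), rng.normal(size=8), np.array([1.0])]
        res = kruskal_wallis_posthoc(groups)
        assert res.df == 1

    def test_two_groups_equals_squared_ranksum_z(self):
        rng = np.random.default_rng(7)
        a = rng.lognormal(6, 1, 30)
        b = rng.lognormal(6.3, 1, 40)
        kw = kruskal_wallis_posthoc([a, b])
        z = rank_sum_test(a, b, method="asymptotic", continuity=False).statistic
        assert kw.statistic == pytest.approx(z**2, rel=1e-9)

    def test_permutation_oracle_on_eight_values(self):
        """{1,2},{3,4},{5,6},{7,8}: the chi-square p agrees with the exact
        permutation distribution of H within the coarseness of an
        enumeration over 2,520 assignments."""
        groups = [np.array([1.0, 2.0]), np.array([3.0, 4.0]),
                  np.array([5.0, 6.0]), np.array([7.0, 8.0])]
        res = kruskal_wallis_posthoc(groups)
        h_obs = kw_statistic(groups)
        assert res.statistic == pytest.approx(h_obs)
        values = np.arange(1.0, 9.0)
        hits = total = 0
        for i1 in combinations(range(8), 2):
            rest1 = [k for k in range(8) if k not in i1]
            for i2 in combinations(rest1, 2):
                rest2 = [k for k in rest1 if k not in i2]
                for i3 in combinations(rest2, 2):
                    i4 = [k for k in rest2 if k not in i3]
                    gs = [values[list(i1)], values[list(i2)],
                          values[list(i3)], values[i4]]
                    total += 1
                    if kw_statistic(gs) >= h_obs - 1e-12:
                        hits += 1
        p_perm = hits / total
        assert total == 2520
        # small pooled samples use exhaustive enumeration: exact agreement
        assert res.p_value == pytest.approx(p_perm, abs=1e-12)
        # the chi-square approximation is available explicitly
        res_asym = kruskal_wallis_posthoc(groups, method="asymptotic")
        assert res_asym.p_value == pytest.approx(sps.chi2.sf(h_obs, 3))

    def test_shifted_group_flagged_by_posthoc(self):
        """Only the three pairs involving the shifted group are significant
        in at least 90% of replicates at this effect size."""
        rng = np.random.default_rng(8)
        n_rep, n, shift = 50, 200, 0.8
        ok = 0
        for _ in range(n_rep):
            gs = {f"g{k}": rng.lognormal(6 + (shift if k == 2 else 0), 1, n)
                  for k in range(4)}
            res = kruskal_wallis_posthoc(gs)
            ph = res.posthoc
            involves = ph["group_a"].eq("g2") | ph["group_b"].eq("g2")
            ok += involves.eq(ph["significant"]).all()
        assert ok / n_rep >= 0.90
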