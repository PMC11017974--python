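"""Rank-sum, proportion-CI, quartile and growth-trend primitives.

Exact rank-sum p-values are cross-checked against an independent published
exact implementation (scipy's Mann-Whitney U) and the normal-approximation
branch against values frozen from R 4.3.3's wilcox.test (continuity and tie
corrected).
"""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from redialab.stats import growth_trend, proportion_ci, quartiles, rank_sum


class TestRankSumExact:
    def test_three_vs_three_shift(self):
        # only 1 of C(6,3)=20 assignments puts all high ranks in one group
        res = rank_sum([4, 5, 6], [1, 2, 3], "greater")
        assert res.exact
        assert res.p_value == pytest.approx(1 / 20)

    def test_four_vs_four_shift(self):
        res = rank_sum([5, 6, 7, 8], [1, 2, 3, 4], "greater")
        assert res.p_value == pytest.approx(1 / 70)

    def test_fully_tied_extreme_groups(self):
        # five 4s vs five 0s: one extreme assignment out of C(10,5)=252
        res = rank_sum([4] * 5, [0] * 5, "greater")
        assert not res.exact  # ties: enumeration is conditional on values
        assert res.p_value == pytest.approx(1 / 252)

    def test_two_sided_doubles_smaller_tail(self):
        res = rank_sum([0.10, 0.11, 0.12], [0.02, 0.02, 0.03], "two_sided")
        assert res.p_value == pytest.approx(2 / 20)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum([], [1, 2])

    @pytest.mark.parametrize("n1", [1, 2, 3, 4])
    def test_exact_matches_independent_implementation_all_partitions(self, n1):
        """All two-group partitions of ranks 1..8 agree with scipy's exact
        Mann-Whitney for every alternative."""
        pooled = list(range(1, 9))
        n2 = 8 - n1
        for idx in itertools.combinations(range(8), n1):
            a = [pooled[i] for i in idx]
            b = [pooled[i] for i in range(8) if i not in idx]
            for alt, scipy_alt in (
                ("greater", "greater"),
                ("less", "less"),
                ("two_sided", "two-sided"),
            ):
                mine = rank_sum(a, b, alt)
                ref = sps.mannwhitneyu(a, b, alternative=scipy_alt, method="exact")
                assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12), (a, b, alt)
                assert mine.U_statistic == pytest.approx(ref.statistic)

    def test_tied_enumeration_matches_brute_force(self):
        """With ties, the conditional permutation p matches a from-scratch
        enumeration over index assignments."""
        a, b = [1.0, 2.0, 2.0, 5.0], [2.0, 3.0, 3.0]
        pooled = a + b
        ranks = sps.rankdata(pooled)
        n1 = len(a)
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2

        def u_of(idx):
            return sum(ranks[i] for i in idx) - n1 * (n1 + 1) / 2

        us = [u_of(idx) for idx in itertools.combinations(range(len(pooled)), n1)]
        expected = sum(u >= u_obs - 1e-12 for u in us) / len(us)
        assert rank_sum(a, b, "greater").p_value == pytest.approx(expected)


class TestRankSumAsymptotic:
    # frozen from R 4.3.3: wilcox.test(a, b, correct=TRUE, exact=FALSE)
    A = [3, 5, 5, 7, 9, 11, 11, 2, 8, 6, 4, 4, 12]
    B = [1, 2, 2, 3, 5, 6, 7, 4, 3, 2, 10, 1]

    def test_matches_r_one_sided(self):
        res = rank_sum(self.A, self.B, "greater")
        assert not res.exact
        assert res.U_statistic == pytest.approx(119.5)
        assert res.p_value == pytest.approx(0.0125020019, abs=1e-9)

    def test_matches_r_two_sided(self):
        res = rank_sum(self.A, self.B, "two_sided")
        assert res.p_value == pytest.approx(0.0250040039, abs=1e-9)

    def test_all_identical_observations_give_p_one(self):
        res = rank_sum([5.0] * 10, [5.0] * 10, "greater", exact_n_max=12)
        assert res.p_value == 1.0


class TestProportionCI:
    @pytest.mark.parametrize("k,n", [(40, 50), (10, 50), (0, 20), (20, 20), (3, 7)])
    def test_matches_beta_quantile_oracle(self, k, n):
        ci = proportion_ci(k, n)
        lo = 0.0 if k == 0 else sps.beta.ppf(0.025, k, n - k + 1)
        hi = 1.0 if k == n else sps.beta.ppf(0.975, k + 1, n - k)
        assert ci.lo == pytest.approx(lo, abs=1e-9)
        assert ci.hi == pytest.approx(hi, abs=1e-9)
        assert ci.lo <= ci.point <= ci.hi

    def test_worked_interval_values(self):
        hi_group = proportion_ci(40, 50)
        lo_group = proportion_ci(10, 50)
        assert (hi_group.lo, hi_group.hi) == pytest.approx((0.663, 0.900), abs=5e-4)
        assert (lo_group.lo, lo_group.hi) == pytest.approx((0.100, 0.337), abs=5e-4)
        assert not hi_group.overlaps(lo_group)

    def test_coverage_under_simulation(self, rng):
        """Clopper-Pearson intervals at p=0.3, n=50 cover at >= nominal rate."""
        p, n, reps = 0.3, 50, 2000
        ks = rng.binomial(n, p, size=reps)
        covered = 0
        cache = {}
        for k in ks:
            if k not in cache:
                ci = proportion_ci(int(k), n)
                cache[k] = (ci.lo, ci.hi)
            lo, hi = cache[k]
            covered += lo <= p <= hi
        assert covered / reps >= 0.95 - 0.01

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            proportion_ci(5, 0)
        with pytest.raises(ValueError):
            proportion_ci(8, 5)


class TestQuartilesAndTrend:
    def test_interpolated_quartiles_worked_example(self):
        assert quartiles([5, 5, 6, 6, 7, 7, 8, 30]) == pytest.approx((5.75, 7.25))

    def test_quartiles_match_brute_force_interpolation(self, rng):
        for _ in range(20):
            v = np.sort(rng.normal(size=rng.integers(4, 30)))
            q1, q3 = quartiles(v)
            for q, p in ((q1, 0.25), (q3, 0.75)):
                h = (len(v) - 1) * p
                lo, frac = int(np.floor(h)), h - np.floor(h)
                expected = v[lo] + frac * (v[min(lo + 1, len(v) - 1)] - v[lo])
                assert q == pytest.approx(expected)

    def test_growth_trend_exact_line(self):
        slope, p = growth_trend([0, 1, 2], [10, 20, 30])
        assert slope == pytest.approx(10)
        assert p <= 1e-10

    def test_growth_trend_flat(self):
        slope, _ = growth_trend([0, 7, 14, 21, 28], [500] * 5)
        assert slope == pytest.approx(0)

    def test_growth_trend_needs_three_points(self):
        with pytest.raises(ValueError):
            growth_trend([0, 1], [10, 20])
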