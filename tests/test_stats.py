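import itertools
import math

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from stonecharge import (
    CorrelationMethod,
    RankTestMethod,
    mann_whitney,
    spearman,
    summarize,
)

# ---------------------------------------------------------------------------
# independent oracles, written from the definitions


def naive_ranks(values):
    """Average ranks computed directly from the definition."""
    values = list(values)
    out = []
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        out.append(less + (equal + 1) / 2.0)
    return out


def pearson(x, y):
    mx, my = sum(x) / len(x), sum(y) / len(y)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def spearman_permutation_oracle(x, y):
    """Full-enumeration two-tailed permutation p for Spearman's rho."""
    rx, ry = naive_ranks(x), naive_ranks(y)
    obs = abs(pearson(rx, ry))
    hits = total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(pearson(rx, list(perm))) >= obs - 1e-12:
            hits += 1
    return hits / total


def mann_whitney_u_oracle(a, b):
    """U for group a by direct pairwise comparison (ties count half)."""
    return sum(1.0 if x > y else 0.5 if x == y else 0.0
               for x in a for y in b)


def mann_whitney_permutation_oracle(a, b):
    """Two-tailed p from brute-force label permutation of the pooled data:
    twice the smaller tail of the permutation null at the observed U."""
    pooled = list(a) + list(b)
    n1 = len(a)
    u_obs = mann_whitney_u_oracle(a, b)
    lo = hi = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = mann_whitney_u_oracle(ga, gb)
        total += 1
        if u <= u_obs + 1e-9:
            lo += 1
        if u >= u_obs - 1e-9:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


# ---------------------------------------------------------------------------


class TestSpearman:
    def test_perfect_monotone_association(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).rho == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1]).rho == pytest.approx(-1.0)

    def test_constant_vector_is_an_error(self):
        with pytest.raises(ValueError, match="rho undefined"):
            spearman([1, 1, 1], [1, 2, 3])

    def test_method_switches_with_sample_size(self):
        small = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        large = spearman(list(range(15)), [7, 3, 11, 0, 9, 1, 14, 2, 8, 5,
                                           12, 4, 13, 6, 10])
        assert small.method is CorrelationMethod.EXACT_PERMUTATION
        assert large.method is CorrelationMethod.T_APPROXIMATION

    @given(st.lists(st.integers(0, 5), min_size=5, max_size=6))
    @settings(max_examples=25)
    def test_exact_p_matches_full_permutation_oracle(self, y):
        x = list(range(len(y)))
        if len(set(y)) < 2:
            return
        result = spearman(x, y)
        assert result.p_two_tailed == pytest.approx(
            spearman_permutation_oracle(x, y))

    def test_rho_matches_scipy_under_ties(self):
        x = [1, 2, 2, 3, 5, 5, 7, 8, 9, 10, 11, 12]
        y = [2, 1, 4, 4, 4, 6, 8, 7, 7, 11, 10, 12]
        assert spearman(x, y).rho == pytest.approx(sps.spearmanr(x, y).statistic)

    @given(st.lists(st.integers(-50, 50), min_size=12, max_size=20, unique=True))
    def test_invariance_under_monotone_transforms(self, xi):
        x = [float(v) for v in xi]
        y = [((-1) ** i) * v for i, v in enumerate(x)]
        base = spearman(x, y)
        warped = spearman([math.exp(v / 50) for v in x], y)
        assert warped.rho == pytest.approx(base.rho)
        assert warped.p_two_tailed == pytest.approx(base.p_two_tailed)

    def test_t_approximation_matches_scipy(self):
        x = list(range(20))
        y = [3, 1, 4, 1, 5, 9, 2, 6, 5, 3, 8, 9, 7, 9, 3, 2, 3, 8, 4, 6]
        ours = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert ours.rho == pytest.approx(ref.statistic)
        assert ours.p_two_tailed == pytest.approx(ref.pvalue, rel=1e-6)


class TestMannWhitney:
    def test_complete_separation_small_n(self):
        result = mann_whitney([1, 2, 3], [4, 5, 6])
        assert result.U == 0
        assert result.p_two_tailed == pytest.approx(0.1)  # 2/20 orderings
        assert result.method is RankTestMethod.EXACT_ENUMERATION

    def test_identical_groups_give_central_U_and_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        result = mann_whitney(a, list(a))
        assert result.U == pytest.approx(len(a) ** 2 / 2.0)
        assert result.p_two_tailed == 1.0

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney([], [1.0])

    @given(st.lists(st.integers(0, 100), min_size=2, max_size=5),
           st.lists(st.integers(0, 100), min_size=2, max_size=5))
    @settings(max_examples=60)
    def test_symmetry_in_group_order(self, a, b):
        r1, r2 = mann_whitney(a, b), mann_whitney(b, a)
        assert r1.U + r2.U == pytest.approx(len(a) * len(b))
        assert r1.p_two_tailed == pytest.approx(r2.p_two_tailed)

    @given(st.lists(st.floats(0, 100), min_size=2, max_size=5),
           st.lists(st.floats(0, 100), min_size=2, max_size=5))
    @settings(max_examples=40)
    def test_exact_p_matches_label_permutation_oracle(self, a, b):
        if set(a) & set(b):
            return  # cross-group ties route to the normal approximation
        result = mann_whitney(a, b)
        assert result.method is RankTestMethod.EXACT_ENUMERATION
        assert result.U == pytest.approx(mann_whitney_u_oracle(a, b))
        assert result.p_two_tailed == pytest.approx(
            mann_whitney_permutation_oracle(a, b))

    def test_normal_approximation_converges_to_exact_at_n15(self):
        """At n1 = n2 = 15 the tie-free approximation tracks the exact p to
        a few thousandths; the continuity correction bounds the worst
        mid-range discrepancy at about +0.008 by construction."""
        rng = np.random.default_rng(7)
        diffs = []
        for _ in range(20):
            a = list(rng.normal(0.0, 1.0, 15))
            b = list(rng.normal(0.8, 1.0, 15))
            ours = mann_whitney(a, b)  # n1+n2 = 30 routes to the approximation
            assert ours.method is RankTestMethod.NORMAL_APPROXIMATION
            exact_p = sps.mannwhitneyu(a, b, alternative="two-sided",
                                       method="exact").pvalue
            diffs.append(abs(ours.p_two_tailed - exact_p))
        assert np.mean(diffs) < 0.005
        assert max(diffs) < 0.01

    def test_exact_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n1, n2 = rng.integers(2, 9, 2)
            a = list(rng.normal(0, 1, n1))
            b = list(rng.normal(0.5, 1, n2))
            ours = mann_whitney(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="exact")
            assert ours.method is RankTestMethod.EXACT_ENUMERATION
            assert ours.p_two_tailed == pytest.approx(ref.pvalue, abs=1e-12)

    def test_approximation_matches_scipy_with_ties(self):
        rng = np.random.default_rng(11)
        a = list(rng.integers(0, 15, 30).astype(float))
        b = list(rng.integers(3, 18, 25).astype(float))
        ours = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        assert ours.method is RankTestMethod.NORMAL_APPROXIMATION
        assert ours.p_two_tailed == pytest.approx(ref.pvalue, rel=1e-9)


class TestSummarize:
    def test_odd_n(self):
        s = summarize([1, 2, 3])
        assert (s.n, s.median, s.mean, s.sd) == (3, 2.0, 2.0, 1.0)

    def test_even_n_midpoint_median(self):
        assert summarize([1, 2, 3, 4]).median == 2.5

    def test_singleton(self):
        s = summarize([5.0])
        assert (s.n, s.median, s.mean, s.sd) == (1, 5.0, 5.0, 0.0)

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            summarize([])
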