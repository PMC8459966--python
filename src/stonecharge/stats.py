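"""Nonparametric two-group statistics: Spearman correlation, Mann-Whitney U.

Both tests are two-tailed and tie-aware. Small samples get an exact null:

* Spearman — rho is the product-moment correlation of average ranks. For
  n <= 7 the permutation p-value enumerates all n! orderings; for
  8 <= n <= 10 a seeded Monte-Carlo permutation (20 000 draws) is used;
  larger n fall back to the Student-t approximation with n-2 degrees of
  freedom. The method actually used is recorded on the result.

* Mann-Whitney — U from rank sums with average ranks for ties. When
  n1 + n2 <= 20 and no value is shared across the two groups, the null
  distribution of U is enumerated exactly over all C(n1+n2, n1) group
  assignments; otherwise the normal approximation with tie correction and
  continuity correction is used. Two-tailed p is twice the smaller tail,
  capped at 1.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrelationMethod",
    "RankTestMethod",
    "CorrelationResult",
    "RankTestResult",
    "GroupSummary",
    "spearman",
    "mann_whitney",
    "summarize",
]

SPEARMAN_EXACT_MAX_N = 7        # full n! enumeration up to here
SPEARMAN_PERMUTATION_MAX_N = 10  # Monte-Carlo permutation up to here
SPEARMAN_MC_DRAWS = 20_000
MANN_WHITNEY_EXACT_MAX_N = 20   # exact enumeration while n1+n2 <= this


class CorrelationMethod(str, Enum):
    EXACT_PERMUTATION = "exact_permutation"
    T_APPROXIMATION = "t_approximation"


class RankTestMethod(str, Enum):
    EXACT_ENUMERATION = "exact_enumeration"
    NORMAL_APPROXIMATION = "normal_approximation"


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_two_tailed: float
    n: int
    method: CorrelationMethod


@dataclass(frozen=True)
class RankTestResult:
    U: float
    p_two_tailed: float
    n1: int
    n2: int
    method: RankTestMethod


@dataclass(frozen=True)
class GroupSummary:
    """n, median, mean and sample standard deviation of one group."""

    n: int
    median: float
    mean: float
    sd: float


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    """Product-moment correlation of two rank vectors (tie-corrected rho)."""
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(x: Sequence[float], y: Sequence[float],
             mc_seed: int = 0) -> CorrelationResult:
    """Two-tailed Spearman rank correlation.

    ``mc_seed`` fixes the Monte-Carlo permutation stream used for
    8 <= n <= 10, keeping results deterministic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rho undefined for a constant vector")

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _rank_rho(rx, ry)

    if n <= SPEARMAN_EXACT_MAX_N:
        target = abs(rho) - 1e-12
        hits = total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_rank_rho(rx, np.array(perm))) >= target:
                hits += 1
        return CorrelationResult(rho, hits / total, n,
                                 CorrelationMethod.EXACT_PERMUTATION)

    if n <= SPEARMAN_PERMUTATION_MAX_N:
        rng = np.random.default_rng(mc_seed)
        target = abs(rho) - 1e-12
        hits = 0
        for _ in range(SPEARMAN_MC_DRAWS):
            if abs(_rank_rho(rx, rng.permutation(ry))) >= target:
                hits += 1
        p = (hits + 1) / (SPEARMAN_MC_DRAWS + 1)
        return CorrelationResult(rho, min(1.0, p), n,
                                 CorrelationMethod.EXACT_PERMUTATION)

    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return CorrelationResult(rho, min(1.0, p), n,
                             CorrelationMethod.T_APPROXIMATION)


def _exact_u_pvalue(ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Exact two-tailed p by enumerating all group assignments of the ranks."""
    n = ranks.size
    base = n1 * (n1 + 1) / 2.0
    lo = hi = total = 0
    for idx in itertools.combinations(range(n), n1):
        u = sum(ranks[i] for i in idx) - base
        total += 1
        if u <= u_obs + 1e-9:
            lo += 1
        if u >= u_obs - 1e-9:
            hi += 1
    # two-tailed p: twice the smaller observed tail, capped at 1. Tails are
    # taken on the realised null (ties can make the mirrored U unattainable).
    return min(1.0, 2.0 * min(lo, hi) / total)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> RankTestResult:
    """Two-tailed Mann-Whitney U test; U is reported for the first group."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    n1n2 = n1 * n2

    cross_ties = bool(set(a.tolist()) & set(b.tolist()))
    if n1 + n2 <= MANN_WHITNEY_EXACT_MAX_N and not cross_ties:
        p = _exact_u_pvalue(ranks, n1, u1)
        return RankTestResult(u1, p, n1, n2, RankTestMethod.EXACT_ENUMERATION)

    n = n1 + n2
    mu = n1n2 / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum()) / (n * (n - 1))
    var = n1n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # every observation identical
        return RankTestResult(u1, 1.0, n1, n2, RankTestMethod.NORMAL_APPROXIMATION)
    u_min = min(u1, n1n2 - u1)
    z = (u_min - mu + 0.5) / math.sqrt(var)  # continuity-corrected lower tail
    p = min(1.0, 2.0 * sps.norm.cdf(z))
    return RankTestResult(u1, p, n1, n2, RankTestMethod.NORMAL_APPROXIMATION)


def summarize(values: Sequence[float]) -> GroupSummary:
    """Median (mid-point rule), mean and sample sd (n-1) of a group."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarise an empty group")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return GroupSummary(
        n=int(v.size),
        median=float(np.median(v)),
        mean=float(np.mean(v)),
        sd=sd,
    )
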