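"""Shared statistical primitives used by several analysis stages.

Only the two tests that multiple stages share live here: a guarded Pearson
correlation and a Wilcoxon rank-sum test that enumerates exactly for small
groups and falls back to the tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

from itertools import combinations
from typing import NamedTuple

import numpy as np
from scipy import stats as sps

from .errors import InvalidInputError, UndefinedCorrelationError

__all__ = ["pearson", "rank_sum_test", "PearsonResult", "RankSumResult"]

#: largest per-group size for which the rank-sum test enumerates exactly
EXACT_GROUP_MAX = 10


class PearsonResult(NamedTuple):
    r: float
    p: float


class RankSumResult(NamedTuple):
    statistic: float  # Mann-Whitney U of the first group
    p: float
    method: str  # "exact" or "asymptotic"
    median_a: float
    median_b: float


def pearson(x, y, min_n: int = 3) -> PearsonResult:
    """Pearson correlation with a two-sided t-distribution p-value (n-2 df).

    Raises
    ------
    InvalidInputError
        if fewer than ``min_n`` paired observations are available.
    UndefinedCorrelationError
        if either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < min_n:
        raise InvalidInputError(f"need >= {min_n} paired observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    r, p = sps.pearsonr(x, y)
    return PearsonResult(float(r), float(p))


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def _exact_ranksum_p(ranks: np.ndarray, m: int, u_obs: float) -> float:
    """Two-sided exact p by enumerating all C(m+n, m) rank splits.

    The two-sided p is the fraction of splits whose U deviates from the null
    mean mn/2 at least as much as the observed U (ties included).
    """
    n_total = ranks.size
    n = n_total - m
    mu = m * n / 2.0
    offset = m * (m + 1) / 2.0
    dev_obs = abs(u_obs - mu) - 1e-12
    count = 0
    total = 0
    for idx in combinations(range(n_total), m):
        u = ranks[list(idx)].sum() - offset
        if abs(u - mu) >= dev_obs:
            count += 1
        total += 1
    return count / total


def rank_sum_test(a, b) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Enumerates all rank splits exactly when both groups have at most
    ``EXACT_GROUP_MAX`` observations (ties handled through midranks);
    otherwise uses the normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    m = a.size
    u_obs = float(ranks[:m].sum() - m * (m + 1) / 2.0)
    if a.size <= EXACT_GROUP_MAX and b.size <= EXACT_GROUP_MAX:
        p = _exact_ranksum_p(ranks, m, u_obs)
        method = "exact"
    else:
        _, p = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        method = "asymptotic"
    return RankSumResult(u_obs, float(min(p, 1.0)), method,
                         float(np.median(a)), float(np.median(b)))
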