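"""Group comparisons and pathway-pathway correlations.

Two-sample comparisons use the Wilcoxon signed-rank test for paired data
and the Wilcoxon rank-sum (Mann-Whitney) test for independent groups, with
one- and two-sided variants.  For small groups the rank-sum p-value comes
from an exact enumeration over all assignments of the pooled (mid)ranks to
the two groups; above the cutoff a normal approximation with midranks, tie
correction and continuity correction is used.  Correlations report both
Pearson and Spearman coefficients; Pearson is surfaced by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "NotEvaluableError",
    "GroupComparison",
    "CorrelationResult",
    "compare_groups",
    "correlate_pathways",
    "WILCOXON_SIGNED_RANK_TWO_SIDED",
    "RANK_SUM_TWO_SIDED",
    "RANK_SUM_ONE_SIDED",
]

WILCOXON_SIGNED_RANK_TWO_SIDED = "wilcoxon_signed_rank_two_sided"
RANK_SUM_TWO_SIDED = "rank_sum_two_sided"
RANK_SUM_ONE_SIDED = "rank_sum_one_sided"

_TESTS = (WILCOXON_SIGNED_RANK_TWO_SIDED, RANK_SUM_TWO_SIDED, RANK_SUM_ONE_SIDED)


class NotEvaluableError(ValueError):
    """The statistic is undefined on this input (e.g. constant data)."""


@dataclass
class GroupComparison:
    group_labels: tuple[str, str]
    n_per_group: tuple[int, int]
    test_name: str
    statistic: float
    p_value: float | None
    method: str  # "exact" | "normal" | "not_evaluable"
    evaluable: bool = True


@dataclass
class CorrelationResult:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int


def _exact_rank_sum_p(a: Sequence[float], b: Sequence[float], alternative: str) -> tuple[float, float]:
    """Exact rank-sum p by enumeration of rank assignments.

    Pools both groups, assigns midranks, and enumerates every choice of
    ``len(a)`` pooled positions for group a.  The statistic is the rank sum
    W of group a.  One-sided p is the tail probability of W at least
    ('greater') or at most ('less') as extreme as observed; two-sided p is
    twice the smaller tail, capped at 1.
    """
    pooled = np.concatenate([np.asarray(a, float), np.asarray(b, float)])
    ranks = sps.rankdata(pooled)  # midranks under ties
    n_a = len(a)
    w_obs = float(ranks[:n_a].sum())
    n_total = len(pooled)
    tol = 1e-9
    count_ge = count_le = total = 0
    for idx in combinations(range(n_total), n_a):
        w = float(ranks[list(idx)].sum())
        total += 1
        if w >= w_obs - tol:
            count_ge += 1
        if w <= w_obs + tol:
            count_le += 1
    p_greater = count_ge / total
    p_less = count_le / total
    if alternative == "greater":
        return w_obs, p_greater
    if alternative == "less":
        return w_obs, p_less
    return w_obs, min(1.0, 2.0 * min(p_greater, p_less))


def _normal_rank_sum_p(a: Sequence[float], b: Sequence[float], alternative: str) -> tuple[float, float]:
    """Rank-sum via the normal approximation (midranks, tie and continuity correction)."""
    result = sps.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return float(result.statistic), float(result.pvalue)


def compare_groups(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    test: str = RANK_SUM_TWO_SIDED,
    alternative: str = "greater",
    exact_cutoff: int = 10,
    group_labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Compare two groups of pathway activity scores.

    ``alternative`` applies to the one-sided rank-sum test only and states
    the direction for group a ('greater' or 'less').  The exact rank-sum
    distribution is enumerated whenever both groups have at most
    ``exact_cutoff`` observations.  The signed-rank test on identical paired
    groups (all-zero differences) is undefined and is reported as a
    not-evaluable result rather than an error.
    """
    if test not in _TESTS:
        raise ValueError(f"unknown test {test!r}; choose one of {_TESTS}")
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("each group needs at least one observation")
    n = (int(a.size), int(b.size))

    if test == WILCOXON_SIGNED_RANK_TWO_SIDED:
        if a.size != b.size:
            raise ValueError("paired signed-rank test requires equal group sizes")
        if np.all(a == b):
            return GroupComparison(group_labels, n, test, math.nan, None, "not_evaluable", False)
        result = sps.wilcoxon(a, b, alternative="two-sided")
        method = "exact" if max(n) <= 25 and not _has_zero_or_tied_diffs(a, b) else "normal"
        return GroupComparison(group_labels, n, test, float(result.statistic), float(result.pvalue), method)

    side = "two-sided" if test == RANK_SUM_TWO_SIDED else alternative
    if side not in ("two-sided", "greater", "less"):
        raise ValueError(f"alternative must be 'greater' or 'less', got {alternative!r}")
    if max(n) <= exact_cutoff:
        statistic, p = _exact_rank_sum_p(a, b, side)
        method = "exact"
    else:
        statistic, p = _normal_rank_sum_p(a, b, side)
        method = "normal"
    return GroupComparison(group_labels, n, test, statistic, p, method)


def _has_zero_or_tied_diffs(a: np.ndarray, b: np.ndarray) -> bool:
    d = a - b
    d = d[d != 0]
    return d.size != np.unique(np.abs(d)).size or np.any(a - b == 0)


def correlate_pathways(
    scores_x: Sequence[float], scores_y: Sequence[float]
) -> CorrelationResult:
    """Pearson and Spearman correlation between two pathway score vectors."""
    x = np.asarray(scores_x, dtype=float)
    y = np.asarray(scores_y, dtype=float)
    if x.size != y.size:
        raise ValueError("score vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise NotEvaluableError("correlation is undefined for a constant input")
    pearson = sps.pearsonr(x, y)
    spearman = sps.spearmanr(x, y)
    return CorrelationResult(
        pearson_r=float(pearson.statistic),
        pearson_p=float(pearson.pvalue),
        spearman_rho=float(spearman.statistic),
        spearman_p=float(spearman.pvalue),
        n=int(x.size),
    )
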