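"""Nonparametric two-group and k-group rank tests.

The two-group test is the Mann-Whitney / Wilcoxon rank-sum test (the
two-sample specialisation of the Kruskal-Wallis test). For small groups the
null distribution is enumerated exactly over all assignments of the pooled
observations, which remains correct under ties; larger groups use the
tie-corrected normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

EXACT_GROUP_MAX = 8


@dataclass
class RankTestResult:
    statistic: float  # Mann-Whitney U of the first group
    p_value: float
    method: str  # "exact" | "asymptotic" | "degenerate"


def rank_sum_test(x, y, exact_max: int = EXACT_GROUP_MAX) -> RankTestResult:
    """Two-sided rank-sum test of two independent samples.

    Exact enumeration is used when the pooled sample has at most
    ``2 * exact_max`` observations (in particular whenever both groups have
    at most ``exact_max``); the two-sided exact p-value is the null
    probability of a rank sum at least as far from its mean as the observed
    one.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    u_stat = _u_statistic(x, y)
    if np.ptp(pooled) == 0:  # no variation at all: any split is as extreme
        return RankTestResult(u_stat, 1.0, "degenerate")
    if x.size + y.size <= 2 * exact_max:
        return RankTestResult(u_stat, _exact_p(x, y), "exact")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return RankTestResult(float(res.statistic), float(res.pvalue), "asymptotic")


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    ranks = stats.rankdata(np.concatenate([x, y]))
    t = ranks[: x.size].sum()
    return float(t - x.size * (x.size + 1) / 2)


def _exact_p(x: np.ndarray, y: np.ndarray) -> float:
    n1 = x.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    observed = ranks[:n1].sum()
    mean = n1 * (len(pooled) + 1) / 2
    threshold = abs(observed - mean) - 1e-9
    hits = 0
    for idx in combinations(range(len(pooled)), n1):
        if abs(ranks[list(idx)].sum() - mean) >= threshold:
            hits += 1
    return hits / comb(len(pooled), n1)


def kruskal_test(*groups) -> tuple[float, float]:
    """Kruskal-Wallis test; two groups fall back to the rank-sum test."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if len(groups) == 2:
        res = rank_sum_test(groups[0], groups[1])
        return res.statistic, res.p_value
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    stat, p = stats.kruskal(*groups)
    return float(stat), float(p)


def significance_stars(p: float) -> str:
    """Star annotation: ``**`` for p<0.01, ``*`` for p<0.05, ``ns`` otherwise."""
    if np.isnan(p):
        return "na"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
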