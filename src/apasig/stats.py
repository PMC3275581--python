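"""Rank tests and multiple-testing utilities shared across the pipeline.

The Mann-Whitney U test switches automatically to exact enumeration of the
permutation null when both groups are small; the exact path handles ties
(which invalidate the classical closed-form null tables) by enumerating the
actual pooled values.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable

import numpy as np
from scipy import stats as sps

__all__ = ["MannWhitneyResult", "mann_whitney", "bh_adjust", "EXACT_MAX_N"]

#: both groups at or below this size -> exact permutation null
EXACT_MAX_N = 8


class MannWhitneyResult:
    """U statistic of the first sample, and a two-sided p-value."""

    __slots__ = ("u", "pvalue", "method")

    def __init__(self, u: float, pvalue: float, method: str):
        self.u = float(u)
        self.pvalue = float(pvalue)
        self.method = method

    def __repr__(self) -> str:  # pragma: no cover
        return f"MannWhitneyResult(u={self.u:g}, pvalue={self.pvalue:g}, method={self.method!r})"


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of x vs y from midranks (tie-aware)."""
    n, m = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    return float(ranks[:n].sum() - n * (n + 1) / 2.0)


def _exact_pvalue(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by full enumeration of group assignments.

    The permutation null of U is symmetric around n*m/2 even under ties, so
    the two-sided p is the probability of |U - nm/2| at least as large as
    observed, over all C(n+m, n) assignments of the pooled values.
    """
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    mid = n * m / 2.0
    d_obs = abs(u_obs - mid)
    hits = 0
    total = 0
    base = n * (n + 1) / 2.0
    for idx in combinations(range(n + m), n):
        u = ranks[list(idx)].sum() - base
        if abs(u - mid) >= d_obs - 1e-9:
            hits += 1
        total += 1
    return hits / total


def mann_whitney(x: Iterable[float], y: Iterable[float], method: str = "auto") -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test of ``x`` vs ``y``.

    Parameters
    ----------
    method
        ``"exact"`` enumerates the permutation null (feasible for small
        groups), ``"asymptotic"`` uses the tie-corrected normal
        approximation with continuity correction, ``"auto"`` picks exact
        when both groups have at most ``EXACT_MAX_N`` observations.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both groups must be non-empty")
    if method == "auto":
        method = "exact" if max(len(x), len(y)) <= EXACT_MAX_N else "asymptotic"
    u = _u_statistic(x, y)
    if np.ptp(np.concatenate([x, y])) == 0:
        # all pooled values identical: no information, p = 1 by convention
        return MannWhitneyResult(u, 1.0, method)
    if method == "exact":
        p = _exact_pvalue(x, y, u)
    elif method == "asymptotic":
        p = float(sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return MannWhitneyResult(u, min(p, 1.0), method)


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in the input order.

    q_(i) = min_{j >= i} m * p_(j) / j, clipped to 1.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
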