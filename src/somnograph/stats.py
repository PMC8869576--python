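"""Rank-based statistics used across the package.

Small-sample two-group comparisons use the exact Mann–Whitney null
distribution (no ties, combined n ≤ 20); otherwise the tie-corrected normal
approximation. Spearman correlation uses an exact permutation p-value for
n ≤ 9 and the t approximation above that.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats as sps

from .errors import InvalidInputError

EXACT_COMBINED_N = 20
SPEARMAN_EXACT_N = 9


def mann_whitney(x, y, alternative: str = "two-sided") -> tuple[float, float, float]:
    """Mann–Whitney U test of x vs y.

    Returns (U, T, p) where U is the U statistic of the first sample and T
    is the rank sum of the second sample (Wilcoxon rank-sum statistic).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise InvalidInputError("both groups must be non-empty")
    combined = np.concatenate((x, y))
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= EXACT_COMBINED_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    ranks = sps.rankdata(combined)
    t_stat = float(np.sum(ranks[x.size:]))
    return float(res.statistic), t_stat, float(res.pvalue)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal–Wallis H with tie correction; returns (H, p).

    Identical values across all groups give H = 0, p = 1 (scipy raises on
    zero-variance input, which for this use is a maximal-tie no-difference
    case).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 1 for a in arrays):
        raise InvalidInputError("Kruskal-Wallis needs >= 2 non-empty groups")
    if np.unique(np.concatenate(arrays)).size == 1:
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        return 0.0
    return float(rx @ ry) / denom


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with an exact permutation p for n ≤ 9.

    The exact two-sided p is the proportion of permutations of one rank
    vector whose |rho| is at least |rho_observed| (ties handled through
    average ranks). Larger samples fall back to the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError("paired samples must have equal length")
    n = x.size
    if n < 3:
        raise InvalidInputError("Spearman correlation needs n >= 3")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _spearman_rho(rx, ry)
    if n > SPEARMAN_EXACT_N:
        return rho, float(sps.spearmanr(x, y).pvalue)
    target = abs(rho) - 1e-12
    hits = 0
    total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(_spearman_rho(rx, np.asarray(perm))) >= target:
            hits += 1
    return rho, hits / total
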