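"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive expected results by exhaustive
enumeration (contiguous 1-D splits, rank assignments) so the tests never
depend on the code paths they check.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
import pytest

from somnograph import EpochSeries, Hypnogram


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def optimal_split_assignment(values: np.ndarray) -> np.ndarray:
    """Globally optimal 2-means partition of a 1-D sample by exhaustive
    search over contiguous splits of the sorted data (the 1-D optimum is
    always a contiguous split). Returns 0/1 labels, 0 = lower cluster."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    x = values[order]
    n = x.size
    best_wss, best_m = np.inf, 1
    for m in range(1, n):
        left, right = x[:m], x[m:]
        wss = np.sum((left - left.mean()) ** 2) + np.sum((right - right.mean()) ** 2)
        if wss < best_wss - 1e-12:
            best_wss, best_m = wss, m
    labels = np.empty(n, dtype=int)
    labels[order[:best_m]] = 0
    labels[order[best_m:]] = 1
    return labels


def mann_whitney_exact_oracle(x, y) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by enumeration over all assignments
    of the pooled ranks to the first group (tie-free data only).

    Returns (U of first sample, two-sided p) where the two-sided p doubles
    the smaller one-sided tail, clipped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate((x, y))
    assert np.unique(pooled).size == pooled.size, "oracle requires tie-free data"
    ranks = pooled.argsort().argsort() + 1
    n1 = x.size
    u_obs = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2)
    n_le = n_ge = total = 0
    for combo in itertools.combinations(ranks, n1):
        u = sum(combo) - n1 * (n1 + 1) / 2
        total += 1
        n_le += u <= u_obs
        n_ge += u >= u_obs
    assert total == comb(pooled.size, n1)
    p = min(1.0, 2.0 * min(n_le, n_ge) / total)
    return u_obs, p


def spearman_exact_oracle(x, y) -> float:
    """Two-sided permutation p for Spearman's rho on tiny tie-free samples."""
    from scipy.stats import rankdata

    rx = rankdata(x)
    ry = rankdata(y)

    def rho(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b) / np.sqrt(float(a @ a) * float(b @ b))

    obs = abs(rho(rx, ry))
    hits = total = 0
    for perm in itertools.permutations(ry):
        total += 1
        hits += abs(rho(rx, np.asarray(perm))) >= obs - 1e-12
    return hits / total


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


@pytest.fixture
def quiet_series() -> EpochSeries:
    """A motionless night: zero activity, mildly varying heart rate."""
    n = 240
    hr = 60.0 + np.sin(np.linspace(0, 6, n))
    return EpochSeries(g_value=np.zeros(n), heart_rate_bpm=hr)


def make_hypnogram(spec: str) -> Hypnogram:
    """Compact hypnogram builder: e.g. 'W*4 L*90 R*20 D*4 R*20'."""
    codes = {"W": 0, "L": 1, "D": 2, "R": 3}
    stages: list[int] = []
    for token in spec.split():
        code, _, count = token.partition("*")
        stages.extend([codes[code]] * (int(count) if count else 1))
    return Hypnogram(np.array(stages))
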