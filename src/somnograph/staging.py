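"""Three-stage sleep classifier for 30-s smartwatch epochs.

The pipeline runs four steps in order:

1. **Sleep/wake** — a Cole–Kripke weighted moving window over epoch activity:
   ``D_t = P * sum_k W_k * A_{t+k}`` for offsets k = −4..+2, with the
   re-fitted scale factor P = 0.01076 and weights (50, 30, 14, 28, 121, 8, 50).
   An epoch is WAKE iff D ≥ 1. Neighbour epochs outside the record contribute
   zero activity.
2. **Light/deep** — a running score over the sleep epochs, starting at 0 and
   clamped below at 0, incremented per the epoch's G-value bin (+1 below 40,
   then −2, −3, −5, −10, −20 for 40–50, 50–80, 80–200, 200–400, 400–600 and
   above). An epoch is DEEP iff its post-update score exceeds the threshold
   (default 0), else LIGHT.
3. **REM from deep** — two-cluster k-means on the heart rate of the DEEP
   epochs, fitted per night; the higher-heart-rate cluster is relabelled REM.
   Sympathetic activation elevates heart rate in REM relative to slow-wave
   sleep, which is what makes the split identifiable.
4. **REM post-processing** — three rules applied once, in order: REM within
   the first 45 min after sleep onset is demoted; separated REM segments
   shorter than 5 min are demoted; non-REM gaps of 3 min or less between two
   REM runs are promoted to REM (WAKE gaps are preserved).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .core import EpochSeries, Hypnogram, Stage, check_aligned, stage_runs
from .errors import DegenerateInputError, InvalidInputError
from .ingest import fill_missing

DEFAULT_CK_WEIGHTS = (50.0, 30.0, 14.0, 28.0, 121.0, 8.0, 50.0)
DEFAULT_CK_SCALE_P = 0.01076
DEFAULT_SCORE_BINS = (
    (0.0, 40.0, +1.0),
    (40.0, 50.0, -2.0),
    (50.0, 80.0, -3.0),
    (80.0, 200.0, -5.0),
    (200.0, 400.0, -10.0),
    (400.0, 600.0, -20.0),
    (600.0, math.inf, -20.0),
)


@dataclass(frozen=True)
class StagingConfig:
    """Every constant of the staging pipeline, with the published defaults.

    ``ck_weights`` are ordered (W−4, W−3, W−2, W−1, W0, W+1, W+2).
    ``cluster_on`` selects whether k-means runs on heart rate in bpm or on
    the equivalent RR interval in ms (a monotone transform; cluster
    membership can differ, so both are exposed).
    """

    ck_weights: tuple[float, ...] = DEFAULT_CK_WEIGHTS
    ck_scale_p: float = DEFAULT_CK_SCALE_P
    score_bins: tuple[tuple[float, float, float], ...] = DEFAULT_SCORE_BINS
    deep_score_threshold: float = 0.0
    kmeans_k: int = 2
    kmeans_max_iter: int = 300
    kmeans_stable_iters: int = 100
    rem_onset_lockout_min: float = 45.0
    rem_min_segment_min: float = 5.0
    rem_gap_merge_min: float = 3.0
    cluster_on: str = "bpm"
    rng_seed: int = 0

    def __post_init__(self):
        if len(self.ck_weights) != 7:
            raise InvalidInputError("ck_weights must list the 7 offsets W−4..W+2")
        if self.ck_scale_p <= 0:
            raise InvalidInputError("ck_scale_p must be positive")
        if self.kmeans_k != 2:
            raise InvalidInputError("the REM split is defined for exactly 2 clusters")
        if self.kmeans_max_iter <= 0 or self.kmeans_stable_iters <= 0:
            raise InvalidInputError("k-means iteration limits must be positive")
        for d in (self.rem_onset_lockout_min, self.rem_min_segment_min,
                  self.rem_gap_merge_min):
            if d <= 0:
                raise InvalidInputError("rule durations must be positive")
        if self.cluster_on not in ("bpm", "rr"):
            raise InvalidInputError("cluster_on must be 'bpm' or 'rr'")
        # bins must partition [0, inf) without overlap
        bins = sorted(self.score_bins)
        if bins[0][0] != 0.0 or not math.isinf(bins[-1][1]):
            raise InvalidInputError("score_bins must cover [0, inf)")
        for (lo, hi, _), (lo2, _, _) in zip(bins, bins[1:]):
            if hi != lo2:
                raise InvalidInputError("score_bins must tile [0, inf) without gaps")

    @classmethod
    def from_file(cls, path) -> "StagingConfig":
        """Load overrides from a flat TOML file (key = field name)."""
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        kwargs = {}
        for key, value in raw.items():
            if key not in cls.__dataclass_fields__:
                raise InvalidInputError(f"unknown staging-config key {key!r}")
            if key == "ck_weights":
                value = tuple(float(v) for v in value)
            elif key == "score_bins":
                value = tuple(
                    (float(lo), math.inf if hi in ("inf", "") else float(hi), float(inc))
                    for lo, hi, inc in value
                )
            kwargs[key] = value
        return cls(**kwargs)


class ColeKripkeResult(NamedTuple):
    d: np.ndarray       # per-epoch Cole–Kripke score
    wake: np.ndarray    # boolean, True where D >= 1


def cole_kripke(epochs: EpochSeries, config: StagingConfig | None = None) -> ColeKripkeResult:
    """Score sleep/wake per epoch from the activity series.

    Epochs outside the record contribute zero activity to their neighbours'
    windows, so the first/last epochs are scored on a truncated sum.
    """
    config = config or StagingConfig()
    g = epochs.g_value
    w = np.asarray(config.ck_weights, dtype=float)
    padded = np.concatenate((np.zeros(4), g, np.zeros(2)))
    # D_t = P * sum_i w[i] * g[t + i - 4]  <=>  sliding dot product
    windows = np.lib.stride_tricks.sliding_window_view(padded, 7)
    d = config.ck_scale_p * windows @ w
    return ColeKripkeResult(d=d, wake=d >= 1.0)


class ScoreResult(NamedTuple):
    score: np.ndarray   # running score (NaN on wake epochs)
    deep: np.ndarray    # boolean, True where the sleep epoch scored DEEP


def _bin_increment(g: float, bins) -> float:
    for lo, hi, inc in bins:
        if lo <= g < hi:
            return inc
    raise InvalidInputError(f"g_value {g} falls outside the score bins")


def light_deep_score(
    epochs: EpochSeries,
    sleep_mask: np.ndarray,
    config: StagingConfig | None = None,
) -> ScoreResult:
    """Accumulate the G-value score over sleep epochs and label light/deep.

    The score starts at 0, adds each sleep epoch's bin increment in time
    order, and is clamped below at 0; an epoch is DEEP iff its post-update
    score exceeds ``deep_score_threshold``. Wake epochs are untouched.
    """
    config = config or StagingConfig()
    sleep_mask = np.asarray(sleep_mask, dtype=bool)
    if sleep_mask.shape != epochs.g_value.shape:
        raise InvalidInputError("sleep_mask length must match the epoch series")
    score = np.full(len(epochs), np.nan)
    deep = np.zeros(len(epochs), dtype=bool)
    running = 0.0
    for t in np.flatnonzero(sleep_mask):
        running = max(0.0, running + _bin_increment(epochs.g_value[t], config.score_bins))
        score[t] = running
        deep[t] = running > config.deep_score_threshold
    return ScoreResult(score=score, deep=deep)


@dataclass
class ClusterModel:
    """Fitted two-cluster 1-D k-means model (centroids sorted ascending)."""

    centroids: tuple[float, float]
    assignment: np.ndarray
    iterations_run: int
    converged: bool
    inertia: float


def _lloyd(values: np.ndarray, init: np.ndarray, max_iter: int) -> ClusterModel:
    c = np.sort(np.asarray(init, dtype=float))
    assign = None
    iterations = 0
    converged = False
    for _ in range(max_iter):
        iterations += 1
        # nearer centroid; ties go to the lower-valued centroid (argmin -> index 0)
        new_assign = (np.abs(values - c[1]) < np.abs(values - c[0])).astype(int)
        if assign is not None and np.array_equal(new_assign, assign):
            # deterministic update: one unchanged assignment pass is a fixed
            # point, which satisfies any stability patience
            converged = True
            assign = new_assign
            break
        assign = new_assign
        for k in (0, 1):
            members = values[assign == k]
            if members.size:
                c[k] = members.mean()
        order = np.argsort(c)
        if order[0] != 0:
            c = c[order]
            assign = 1 - assign
    inertia = float(np.sum((values - c[assign]) ** 2))
    return ClusterModel(
        centroids=(float(c[0]), float(c[1])),
        assignment=assign,
        iterations_run=iterations,
        converged=converged,
        inertia=inertia,
    )


def _optimal_split_means(values: np.ndarray) -> np.ndarray:
    """Means of the two halves of the WSS-optimal contiguous split (1-D, K=2)."""
    x = np.sort(values)
    n = x.size
    csum = np.cumsum(x)
    csq = np.cumsum(x**2)
    m = np.arange(1, n)  # left part sizes
    left_ss = csq[m - 1] - csum[m - 1] ** 2 / m
    right_sum = csum[-1] - csum[m - 1]
    right_ss = (csq[-1] - csq[m - 1]) - right_sum**2 / (n - m)
    best = int(np.argmin(left_ss + right_ss)) + 1
    return np.array([csum[best - 1] / best, (csum[-1] - csum[best - 1]) / (n - best)])


def kmeans_1d(
    values: Sequence[float],
    config: StagingConfig | None = None,
    rng: np.random.Generator | None = None,
) -> ClusterModel:
    """Two-cluster k-means on a 1-D sample (Lloyd's iteration).

    Initialisation uses a deterministic portfolio — a seeded draw of two
    distinct observed values, the (min, max) pair, and the subset means of
    the exact optimal contiguous split — and keeps the run with the lowest
    within-cluster sum of squares. The portfolio guarantees the global
    optimum in 1-D, where a single random start can stall on a suboptimal
    Lloyd fixed point.
    """
    config = config or StagingConfig()
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InvalidInputError("k-means needs at least 2 values")
    distinct = np.unique(values)
    if distinct.size < 2:
        raise DegenerateInputError("all values identical; no two-cluster structure")
    rng = rng or np.random.default_rng(config.rng_seed)
    inits = [
        rng.choice(distinct, size=2, replace=False),
        np.array([distinct[0], distinct[-1]]),
        _optimal_split_means(values),
    ]
    best = None
    for init in inits:
        model = _lloyd(values, init, config.kmeans_max_iter)
        if best is None or model.inertia < best.inertia - 1e-12:
            best = model
    return best


def rem_from_deep(
    epochs: EpochSeries,
    hypnogram: Hypnogram,
    config: StagingConfig | None = None,
) -> tuple[Hypnogram, ClusterModel | None]:
    """Split the DEEP epochs into deep sleep and REM by heart-rate cluster.

    Fitted per night. The higher-heart-rate cluster becomes REM. If the
    heart rate over the DEEP epochs is degenerate (fewer than 2 distinct
    values) the night keeps its DEEP labels and is flagged.
    """
    config = config or StagingConfig()
    check_aligned(epochs, hypnogram)
    if np.any(hypnogram.stages == int(Stage.REM)):
        raise InvalidInputError("hypnogram already contains REM labels")
    deep_idx = np.flatnonzero(hypnogram.stages == int(Stage.DEEP))
    if deep_idx.size == 0:
        return hypnogram, None
    hr = epochs.heart_rate_bpm[deep_idx]
    if not np.all(np.isfinite(hr)):
        raise InvalidInputError("heart rate missing on DEEP epochs; fill before staging")
    values = hr if config.cluster_on == "bpm" else 60000.0 / hr
    if np.unique(values).size < 2 or deep_idx.size < 2:
        warnings.warn("degenerate heart rate among DEEP epochs; REM split skipped",
                      stacklevel=2)
        return hypnogram.replace(hypnogram.stages, extra_flags=("degenerate_hr",)), None
    model = kmeans_1d(values, config)
    # cluster with the higher mean bpm is REM (for RR clustering the lower
    # RR centroid is the faster heart rate)
    rem_cluster = 1 if config.cluster_on == "bpm" else 0
    stages = hypnogram.stages.copy()
    stages[deep_idx[model.assignment == rem_cluster]] = int(Stage.REM)
    return hypnogram.replace(stages), model


def _epochs_per_min(epoch_seconds: float) -> float:
    return 60.0 / epoch_seconds


def rem_postprocess(
    hypnogram: Hypnogram,
    config: StagingConfig | None = None,
    epoch_seconds: float = 30.0,
) -> Hypnogram:
    """Apply the three REM correction rules, once each, in order.

    1. REM inside the first 45 min after sleep onset (first non-WAKE epoch)
       is demoted to DEEP.
    2. Separated REM segments shorter than 5 min are demoted to DEEP.
    3. Runs of LIGHT/DEEP lasting 3 min or less flanked by REM on both sides
       are promoted to REM; runs containing WAKE are preserved.

    Demotions target DEEP because the epochs were DEEP before the heart-rate
    split. The composed operator is idempotent.
    """
    config = config or StagingConfig()
    per_min = _epochs_per_min(epoch_seconds)
    stages = hypnogram.stages.copy()
    rem, deep = int(Stage.REM), int(Stage.DEEP)

    # rule 1: onset lockout
    non_wake = np.flatnonzero(stages != int(Stage.WAKE))
    if non_wake.size:
        onset = non_wake[0]
        lockout_end = onset + int(round(config.rem_onset_lockout_min * per_min))
        window = np.arange(len(stages)) < lockout_end
        stages[window & (stages == rem)] = deep

    # rule 2: short REM segments
    min_len = int(round(config.rem_min_segment_min * per_min))
    for start, stop, label in stage_runs(stages):
        if label == rem and (stop - start) < min_len:
            stages[start:stop] = deep

    # rule 3: brief sleep-internal non-REM gaps between REM runs
    max_gap = int(round(config.rem_gap_merge_min * per_min))
    runs = stage_runs(stages)
    rem_run_ids = [i for i, (_, _, label) in enumerate(runs) if label == rem]
    for a, b in zip(rem_run_ids, rem_run_ids[1:]):
        gap = runs[a + 1:b]
        gap_len = sum(stop - start for start, stop, _ in gap)
        if gap_len <= max_gap and all(
            label in (int(Stage.LIGHT), deep) for _, _, label in gap
        ):
            stages[runs[a][1]:runs[b][0]] = rem

    return hypnogram.replace(stages)


@dataclass
class StagingResult:
    """Full diagnostics of a staged night."""

    hypnogram: Hypnogram
    d_score: np.ndarray
    sleep_score: np.ndarray
    cluster: ClusterModel | None


def stage_night_detailed(
    epochs: EpochSeries, config: StagingConfig | None = None
) -> StagingResult:
    """Run the full pipeline and keep intermediate diagnostics."""
    config = config or StagingConfig()
    hr = epochs.heart_rate_bpm
    if not np.all(np.isfinite(hr)):
        filled, _ = fill_missing(hr)
        epochs = EpochSeries(epochs.g_value, filled, epochs.epoch_seconds)
    ck = cole_kripke(epochs, config)
    sleep = ~ck.wake
    ld = light_deep_score(epochs, sleep, config)
    stages = np.full(len(epochs), int(Stage.WAKE), dtype=np.int8)
    stages[sleep & ld.deep] = int(Stage.DEEP)
    stages[sleep & ~ld.deep] = int(Stage.LIGHT)
    hyp, model = rem_from_deep(epochs, Hypnogram(stages), config)
    final = rem_postprocess(hyp, config, epoch_seconds=epochs.epoch_seconds)
    return StagingResult(
        hypnogram=final, d_score=ck.d, sleep_score=ld.score, cluster=model
    )


def stage_night(epochs: EpochSeries, config: StagingConfig | None = None) -> Hypnogram:
    """Stage a night: sleep/wake, light/deep, REM split, REM cleanup."""
    return stage_night_detailed(epochs, config).hypnogram
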