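"""Abnormal-REM quantification and data-driven G-threshold selection.

REM sleep behaviour disorder manifests as movement during REM, visible as
high-G epochs inside REM periods. The index is the percentage of REM minutes
whose G-value exceeds a threshold:

    % abnormal REM = 100 * n / T

with n the number of suprathreshold REM minutes and T the total REM minutes.
The threshold itself is selected by sweeping a candidate grid (default 1200
to 4500 in steps of 300) and keeping the value at which a two-sided
Mann–Whitney test best separates a control cohort from a patient cohort
(minimal p; ties broken toward the smaller threshold). The operating default
threshold is 1500.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import EpochSeries, Hypnogram, Stage, check_aligned, stage_runs
from .errors import InvalidInputError
from .stats import mann_whitney

DEFAULT_THRESHOLD = 1500.0
DEFAULT_SWEEP_THRESHOLDS = tuple(float(t) for t in range(1200, 4501, 300))

MINUTE_AGGREGATORS = ("max", "mean")
SWEEP_STATISTICS = ("minutes", "percent", "g_median")


@dataclass(frozen=True)
class AbnormalRemResult:
    """Numerator, denominator and percentage of the abnormal-REM index."""

    n_abnormal_min: int
    total_rem_min: int
    percent: float
    threshold: float
    no_rem: bool = False


def rem_minute_aggregates(
    epochs: EpochSeries, hypnogram: Hypnogram, minute_agg: str = "max"
) -> np.ndarray:
    """Per-minute G aggregates over the REM epochs.

    The pipeline is epoch-based while the index counts minutes: within each
    contiguous REM run, consecutive epoch pairs form minutes and a trailing
    single epoch counts as one minute. Each minute's G is the max (or mean)
    of its epochs' G-values.
    """
    check_aligned(epochs, hypnogram)
    if minute_agg not in MINUTE_AGGREGATORS:
        raise InvalidInputError(f"minute_agg must be one of {MINUTE_AGGREGATORS}")
    agg = np.max if minute_agg == "max" else np.mean
    out = []
    for start, stop, label in stage_runs(hypnogram.stages):
        if label != int(Stage.REM):
            continue
        for a in range(start, stop, 2):
            out.append(float(agg(epochs.g_value[a:min(a + 2, stop)])))
    return np.asarray(out, dtype=float)


def abnormal_rem_percent(
    epochs: EpochSeries,
    hypnogram: Hypnogram,
    threshold: float = DEFAULT_THRESHOLD,
    minute_agg: str = "max",
) -> AbnormalRemResult:
    """Percentage of REM minutes whose G-value exceeds ``threshold``.

    A night without REM reports 0% with the ``no_rem`` flag set rather than
    an undefined division.
    """
    if threshold <= 0:
        raise InvalidInputError("threshold must be positive")
    minutes = rem_minute_aggregates(epochs, hypnogram, minute_agg)
    total = minutes.size
    if total == 0:
        return AbnormalRemResult(0, 0, 0.0, threshold, no_rem=True)
    n_abn = int(np.sum(minutes > threshold))
    return AbnormalRemResult(n_abn, total, 100.0 * n_abn / total, threshold)


@dataclass(frozen=True)
class SweepEntry:
    threshold: float
    u_stat: float
    t_stat: float
    p_value: float
    median_control: float
    median_pd: float


@dataclass(frozen=True)
class SweepResult:
    entries: tuple[SweepEntry, ...]
    chosen: float

    @property
    def thresholds(self) -> tuple[float, ...]:
        return tuple(e.threshold for e in self.entries)

    def entry(self, threshold: float) -> SweepEntry:
        for e in self.entries:
            if e.threshold == threshold:
                return e
        raise KeyError(threshold)


def _subject_statistic(
    night: tuple[EpochSeries, Hypnogram],
    threshold: float,
    statistic: str,
    minute_agg: str,
) -> float:
    epochs, hyp = night
    if statistic == "g_median":
        minutes = rem_minute_aggregates(epochs, hyp, minute_agg)
        above = minutes[minutes > threshold]
        return float(np.median(above)) if above.size else 0.0
    res = abnormal_rem_percent(epochs, hyp, threshold, minute_agg)
    return float(res.n_abnormal_min) if statistic == "minutes" else res.percent


def threshold_sweep(
    control: Sequence[tuple[EpochSeries, Hypnogram]],
    pd_group: Sequence[tuple[EpochSeries, Hypnogram]],
    thresholds: Sequence[float] = DEFAULT_SWEEP_THRESHOLDS,
    statistic: str = "minutes",
    minute_agg: str = "max",
) -> SweepResult:
    """Mann–Whitney sweep over candidate G thresholds.

    Per threshold, each subject is summarised (abnormal REM minutes by
    default; ``percent`` or the median suprathreshold minute G are exposed
    as alternatives) and the two cohorts compared by a two-sided
    Mann–Whitney test. The chosen threshold minimises p, with ties broken
    toward the smaller threshold.
    """
    if len(control) < 2 or len(pd_group) < 2:
        raise InvalidInputError("both cohorts need at least 2 subjects")
    if statistic not in SWEEP_STATISTICS:
        raise InvalidInputError(f"statistic must be one of {SWEEP_STATISTICS}")
    if not thresholds:
        raise InvalidInputError("threshold list is empty")
    entries = []
    for thr in sorted(float(t) for t in thresholds):
        c_vals = [_subject_statistic(nt, thr, statistic, minute_agg) for nt in control]
        p_vals = [_subject_statistic(nt, thr, statistic, minute_agg) for nt in pd_group]
        u, t, p = mann_whitney(c_vals, p_vals, alternative="two-sided")
        entries.append(
            SweepEntry(
                threshold=thr,
                u_stat=u,
                t_stat=t,
                p_value=p,
                median_control=float(np.median(c_vals)),
                median_pd=float(np.median(p_vals)),
            )
        )
    best = min(entries, key=lambda e: (e.p_value, e.threshold))
    return SweepResult(entries=tuple(entries), chosen=best.threshold)
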