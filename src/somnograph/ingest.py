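"""Reduce raw wrist-sensor streams to aligned 30-s epochs, and read/write
epoch tables.

The accelerometer is sampled at a nominal 250 Hz; the per-epoch activity
magnitude (G-value) is the maximum dynamic acceleration |‖a‖ − 1 g| within
each non-overlapping 30-s window, reported in milli-g. Beat-to-beat (RR)
intervals from the PPG sensor are aggregated to a per-epoch mean heart rate
(60000 / mean RR in ms); epochs without beats are filled from the nearest
epoch that has one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EPOCH_SECONDS, EpochSeries, Hypnogram, Stage, parse_stage_label
from .errors import InvalidInputError, MalformedInputError

#: physiological RR bounds used to discard artefactual beats, in ms
RR_BOUNDS_MS = (200.0, 4000.0)

G_AGGREGATORS = {
    "max": np.max,
    "mean": np.mean,
    "sum": np.sum,
}


@dataclass
class RawAccelTrace:
    """A raw 3-axis accelerometer trace, axes in g, timestamps in seconds."""

    timestamps: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    nominal_rate: float = 250.0

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if self.timestamps.size == 0:
            raise InvalidInputError("accelerometer trace is empty")
        for axis in (self.ax, self.ay, self.az):
            if axis.shape != self.timestamps.shape:
                raise InvalidInputError("axis series must match timestamps length")
        if np.any(np.diff(self.timestamps) < 0):
            raise MalformedInputError("timestamps must be monotone non-decreasing")
        if self.nominal_rate <= 0:
            raise InvalidInputError("nominal_rate must be positive")

    @property
    def magnitude_g(self) -> np.ndarray:
        return np.sqrt(self.ax**2 + self.ay**2 + self.az**2)


@dataclass
class RRSeries:
    """Beat times (s, strictly increasing) and RR intervals (ms, positive)."""

    beat_times: np.ndarray
    rr_ms: np.ndarray

    def __post_init__(self):
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if self.beat_times.size == 0:
            raise InvalidInputError("RR series is empty")
        if self.rr_ms.shape != self.beat_times.shape:
            raise InvalidInputError("beat_times and rr_ms lengths differ")
        if np.any(np.diff(self.beat_times) <= 0):
            raise MalformedInputError("beat_times must be strictly increasing")
        if np.any(self.rr_ms <= 0):
            raise InvalidInputError("rr_ms must be positive")

    def cleaned(self) -> "RRSeries":
        """Drop intervals outside the physiological window RR_BOUNDS_MS."""
        lo, hi = RR_BOUNDS_MS
        keep = (self.rr_ms > lo) & (self.rr_ms < hi)
        if not np.any(keep):
            raise InvalidInputError("no RR intervals survive physiological cleaning")
        return RRSeries(self.beat_times[keep], self.rr_ms[keep])


def epoch_activity(
    trace: RawAccelTrace,
    epoch_seconds: float = EPOCH_SECONDS,
    aggregator: str = "max",
) -> EpochSeries:
    """Epoch a raw trace into per-window G-values (milli-g).

    Windows start at the first sample's timestamp and are non-overlapping;
    the trailing partial window is dropped, so the epoch count is
    floor(duration / epoch_seconds). The per-window statistic defaults to
    the max of |magnitude − 1 g| but may be ``mean`` or ``sum`` to suit
    devices reporting integrated activity counts.
    """
    if epoch_seconds <= 0:
        raise InvalidInputError("epoch_seconds must be positive")
    try:
        agg = G_AGGREGATORS[aggregator]
    except KeyError:
        raise InvalidInputError(f"unknown aggregator {aggregator!r}") from None
    t0 = trace.timestamps[0]
    duration = trace.timestamps[-1] - t0
    n = int(np.floor(duration / epoch_seconds))
    if n < 1:
        raise InvalidInputError(
            f"trace spans {duration:.1f} s, shorter than one {epoch_seconds:g}-s epoch"
        )
    dynamic_mg = np.abs(trace.magnitude_g - 1.0) * 1000.0
    idx = np.floor((trace.timestamps - t0) / epoch_seconds).astype(int)
    g = np.zeros(n)
    for e in range(n):
        sel = dynamic_mg[idx == e]
        g[e] = agg(sel) if sel.size else 0.0
    return EpochSeries(g_value=g, epoch_seconds=epoch_seconds)


def fill_missing(values: np.ndarray) -> tuple[np.ndarray, int]:
    """Nearest-neighbour fill of NaNs (ties broken toward the earlier epoch).

    Returns the filled array and the number of epochs filled.
    """
    values = np.asarray(values, dtype=float).copy()
    present = np.flatnonzero(np.isfinite(values))
    missing = np.flatnonzero(~np.isfinite(values))
    if missing.size == 0:
        return values, 0
    if present.size == 0:
        raise InvalidInputError("no observed values to fill from")
    # position of each missing index among the observed ones
    pos = np.searchsorted(present, missing)
    left = present[np.clip(pos - 1, 0, present.size - 1)]
    right = present[np.clip(pos, 0, present.size - 1)]
    dl = np.abs(missing - left)
    dr = np.abs(right - missing)
    nearest = np.where(dl <= dr, left, right)  # tie -> earlier epoch
    values[missing] = values[nearest]
    return values, int(missing.size)


def epoch_heart_rate(
    rr: RRSeries,
    n_epochs: int,
    epoch_seconds: float = EPOCH_SECONDS,
    t0: float = 0.0,
) -> np.ndarray:
    """Per-epoch mean heart rate (bpm) from an RR series.

    Heart rate for an epoch is 60000 / mean(rr_ms of beats in the window);
    windows are [t0 + i*epoch_seconds, t0 + (i+1)*epoch_seconds). Epochs
    with no beats are filled from the nearest epoch with beats.
    """
    if n_epochs <= 0:
        raise InvalidInputError("n_epochs must be positive")
    if epoch_seconds <= 0:
        raise InvalidInputError("epoch_seconds must be positive")
    rr = rr.cleaned()
    idx = np.floor((rr.beat_times - t0) / epoch_seconds).astype(int)
    hr = np.full(n_epochs, np.nan)
    in_range = (idx >= 0) & (idx < n_epochs)
    for e in np.unique(idx[in_range]):
        hr[e] = 60000.0 / np.mean(rr.rr_ms[idx == e])
    if not np.any(np.isfinite(hr)):
        raise InvalidInputError("no beats fall inside the epoch grid")
    hr, n_filled = fill_missing(hr)
    if n_filled:
        warnings.warn(
            f"filled heart rate for {n_filled} epoch(s) from nearest neighbour",
            stacklevel=2,
        )
    return hr


# ---------------------------------------------------------------------------
# epoch-table CSV dialect: epoch_index,g_value,heart_rate_bpm[,stage]
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("epoch_index", "g_value", "heart_rate_bpm")


def read_epoch_table(path) -> tuple[EpochSeries, Hypnogram | None]:
    """Read an epoch table CSV; returns the series and, when present, stages.

    Stage labels may be canonical (WAKE/LIGHT/DEEP/REM) or PSG-dialect
    (0/W, 1/2/N1/N2, 3/4/N3, 5/R). Missing columns, non-numeric cells,
    duplicated or gapped epoch_index raise MalformedInputError with the
    offending line number (1-based, counting the header as line 1).
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except (OSError, pd.errors.ParserError) as exc:
        raise MalformedInputError(f"cannot read epoch table {path}: {exc}") from exc
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise MalformedInputError(f"{path}: missing required column {col!r}", line=1)
    numeric = {}
    for col in REQUIRED_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        raw = df[col]
        bad = vals.isna() & ~(raw.isna() | (raw.str.strip() == ""))
        if col == "epoch_index" and (vals.isna()).any():
            bad = vals.isna()
        if bad.any():
            row = int(bad.idxmax())
            raise MalformedInputError(
                f"{path}: non-numeric value {df[col][row]!r} in column {col!r}",
                line=row + 2,
            )
        # parse with float(): pandas' fast parser is not round-trip exact
        numeric[col] = np.array(
            [
                float(s) if isinstance(s, str) and s.strip() != "" else np.nan
                for s in raw
            ],
            dtype=float,
        )
    idx = numeric["epoch_index"]
    expected = np.arange(len(idx), dtype=float)
    if not np.array_equal(idx, expected):
        row = int(np.flatnonzero(idx != expected)[0])
        kind = "duplicate" if row and idx[row] == idx[row - 1] else "gap or disorder"
        raise MalformedInputError(
            f"{path}: {kind} in epoch_index (saw {idx[row]:g}, expected {row})",
            line=row + 2,
        )
    series = EpochSeries(
        g_value=numeric["g_value"], heart_rate_bpm=numeric["heart_rate_bpm"]
    )
    hyp = None
    if "stage" in df.columns:
        labels = df["stage"]
        try:
            stages = np.array([int(parse_stage_label(s)) for s in labels])
        except InvalidInputError as exc:
            raise MalformedInputError(f"{path}: {exc}") from exc
        hyp = Hypnogram(stages, provenance="reference")
    return series, hyp


def write_epoch_table(path, epochs: EpochSeries, hypnogram: Hypnogram | None = None) -> None:
    """Write an epoch table CSV (round-trip lossless for finite values)."""
    data = {
        "epoch_index": epochs.epoch_index,
        "g_value": epochs.g_value,
        "heart_rate_bpm": epochs.heart_rate_bpm,
    }
    if hypnogram is not None:
        if len(hypnogram) != len(epochs):
            raise InvalidInputError("hypnogram length must match epoch series")
        data["stage"] = hypnogram.stage_names()
    # default float formatting is the shortest exact repr, so finite values
    # round-trip losslessly
    pd.DataFrame(data).to_csv(path, index=False)
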