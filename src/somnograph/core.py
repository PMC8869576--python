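"""Core containers shared by every stage of the pipeline.

The atomic unit throughout is the 30-second scoring epoch. A night is
represented as an :class:`EpochSeries` (per-epoch activity magnitude, the
"G-value", plus mean heart rate) and a :class:`Hypnogram` (per-epoch stage
label drawn from WAKE / LIGHT / DEEP / REM). Coarser views — NREM as
LIGHT∪DEEP, SLEEP as everything non-WAKE — are derived on demand and never
stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .errors import InvalidInputError

EPOCH_SECONDS = 30.0
#: epochs per minute at the standard 30-s epoch length
EPOCHS_PER_MINUTE = 2

HR_LOW, HR_HIGH = 20.0, 250.0  # plausible bpm bounds (exclusive)


class Stage(IntEnum):
    """Sleep-stage labels, ordered WAKE, LIGHT, DEEP, REM."""

    WAKE = 0
    LIGHT = 1
    DEEP = 2
    REM = 3


STAGE_NAMES = {s: s.name for s in Stage}

#: label dialect accepted for reference hypnograms (PSG-style exports):
#: AASM numeric scores and letter codes map onto the 4-label scheme.
REFERENCE_LABEL_MAP = {
    "0": Stage.WAKE,
    "W": Stage.WAKE,
    "WAKE": Stage.WAKE,
    "1": Stage.LIGHT,
    "2": Stage.LIGHT,
    "N1": Stage.LIGHT,
    "N2": Stage.LIGHT,
    "LIGHT": Stage.LIGHT,
    "3": Stage.DEEP,
    "4": Stage.DEEP,
    "N3": Stage.DEEP,
    "DEEP": Stage.DEEP,
    "5": Stage.REM,
    "R": Stage.REM,
    "REM": Stage.REM,
}


def parse_stage_label(label) -> Stage:
    """Map a stage label (canonical or PSG dialect) onto a :class:`Stage`."""
    if isinstance(label, Stage):
        return label
    key = str(label).strip().upper()
    # "3.0" style numerics from CSV round-trips
    if key.endswith(".0"):
        key = key[:-2]
    try:
        return REFERENCE_LABEL_MAP[key]
    except KeyError:
        raise InvalidInputError(f"unknown stage label: {label!r}") from None


@dataclass
class EpochSeries:
    """Aligned per-epoch G-values and heart rate for one night.

    g_value
        Non-negative activity magnitude per epoch, in device activity units.
    heart_rate_bpm
        Mean heart rate per epoch; NaN where no beats were observed.
    """

    g_value: np.ndarray
    heart_rate_bpm: np.ndarray = None  # type: ignore[assignment]
    epoch_seconds: float = EPOCH_SECONDS

    def __post_init__(self):
        self.g_value = np.asarray(self.g_value, dtype=float)
        if self.heart_rate_bpm is None:
            self.heart_rate_bpm = np.full(self.g_value.shape, np.nan)
        self.heart_rate_bpm = np.asarray(self.heart_rate_bpm, dtype=float)
        if self.g_value.ndim != 1:
            raise InvalidInputError("g_value must be one-dimensional")
        if self.g_value.size == 0:
            raise InvalidInputError("EpochSeries must contain at least one epoch")
        if self.heart_rate_bpm.shape != self.g_value.shape:
            raise InvalidInputError("g_value and heart_rate_bpm lengths differ")
        if not np.all(np.isfinite(self.g_value)):
            raise InvalidInputError("g_value must be finite")
        if np.any(self.g_value < 0):
            raise InvalidInputError("g_value must be non-negative")
        present = np.isfinite(self.heart_rate_bpm)
        hr = self.heart_rate_bpm[present]
        if hr.size and (np.any(hr <= HR_LOW) or np.any(hr >= HR_HIGH)):
            raise InvalidInputError(
                f"heart_rate_bpm must lie in ({HR_LOW:g}, {HR_HIGH:g}) bpm"
            )
        if self.epoch_seconds <= 0:
            raise InvalidInputError("epoch_seconds must be positive")

    def __len__(self) -> int:
        return self.g_value.size

    @property
    def n_epochs(self) -> int:
        return self.g_value.size

    @property
    def epoch_index(self) -> np.ndarray:
        return np.arange(self.n_epochs)

    @property
    def duration_min(self) -> float:
        return self.n_epochs * self.epoch_seconds / 60.0


@dataclass
class Hypnogram:
    """Per-epoch stage labels for one night."""

    stages: np.ndarray
    provenance: str = "predicted"
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        stages = np.asarray(self.stages)
        if stages.dtype.kind not in "iu":
            stages = np.array([parse_stage_label(s) for s in stages])
        self.stages = stages.astype(np.int8)
        if self.stages.ndim != 1 or self.stages.size == 0:
            raise InvalidInputError("Hypnogram must be a non-empty 1-D label series")
        if np.any((self.stages < 0) | (self.stages > 3)):
            raise InvalidInputError("stage labels must be WAKE/LIGHT/DEEP/REM")
        if self.provenance not in ("predicted", "reference"):
            raise InvalidInputError("provenance must be 'predicted' or 'reference'")

    def __len__(self) -> int:
        return self.stages.size

    def mask(self, *stages: Stage) -> np.ndarray:
        out = np.zeros(self.stages.shape, dtype=bool)
        for s in stages:
            out |= self.stages == int(s)
        return out

    @property
    def sleep_mask(self) -> np.ndarray:
        """Epochs scored as sleep (anything non-WAKE)."""
        return self.stages != int(Stage.WAKE)

    def replace(self, stages: np.ndarray, extra_flags: tuple[str, ...] = ()) -> "Hypnogram":
        return Hypnogram(stages, provenance=self.provenance,
                         flags=self.flags + tuple(extra_flags))

    def stage_names(self) -> list[str]:
        return [Stage(int(s)).name for s in self.stages]


def stage_runs(stages: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode a label series as (start, stop, label) with stop exclusive."""
    stages = np.asarray(stages)
    if stages.size == 0:
        return []
    change = np.flatnonzero(np.diff(stages)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [stages.size]))
    return [(int(a), int(b), int(stages[a])) for a, b in zip(starts, stops)]


def check_aligned(epochs: EpochSeries, hypnogram: Hypnogram) -> None:
    if len(epochs) != len(hypnogram):
        raise InvalidInputError(
            f"epoch series ({len(epochs)}) and hypnogram ({len(hypnogram)}) "
            "must have equal length"
        )
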