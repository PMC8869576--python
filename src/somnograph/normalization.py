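"""Cross-device G-value scaling.

Activity magnitudes recorded by different wrist sensors live on different
scales; the staging thresholds assume the reference device's range. A source
recording is mapped into that range by a single multiplicative factor fitted
from the extrema of the two devices, by one of three methods:

- ``range_ratio``: (Gmax − Gmin) / (Gdmax − Gdmin)
- ``max_ratio``:   Gmax / Gdmax
- ``min_ratio``:   Gmin / Gdmin  (default; best-performing in validation)

where G refers to the reference device and Gd to the source device.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EpochSeries
from .errors import InvalidInputError

METHODS = ("range_ratio", "max_ratio", "min_ratio")


@dataclass(frozen=True)
class ScalingSpec:
    """Extrema of the reference (g_*) and source (gd_*) devices."""

    g_max: float
    g_min: float
    gd_max: float
    gd_min: float
    method: str = "min_ratio"

    def __post_init__(self):
        if self.method not in METHODS:
            raise InvalidInputError(f"method must be one of {METHODS}")
        if not (self.g_max > self.g_min >= 0):
            raise InvalidInputError("reference extrema must satisfy g_max > g_min >= 0")
        if self.gd_max < self.gd_min or self.gd_min < 0:
            raise InvalidInputError("source extrema must satisfy gd_max >= gd_min >= 0")

    @classmethod
    def from_series(
        cls, reference: EpochSeries, source: EpochSeries, method: str = "min_ratio"
    ) -> "ScalingSpec":
        """Fit extrema over whole recordings (per subject-night)."""
        return cls(
            g_max=float(np.max(reference.g_value)),
            g_min=float(np.min(reference.g_value)),
            gd_max=float(np.max(source.g_value)),
            gd_min=float(np.min(source.g_value)),
            method=method,
        )


def fit_scale(spec: ScalingSpec) -> float:
    """Compute the scale factor for the spec's method."""
    if spec.method == "range_ratio":
        denom = spec.gd_max - spec.gd_min
    elif spec.method == "max_ratio":
        denom = spec.gd_max
    else:
        denom = spec.gd_min
    if denom == 0:
        raise InvalidInputError(
            f"{spec.method}: source extrema give a zero denominator"
        )
    if spec.method == "range_ratio":
        return (spec.g_max - spec.g_min) / denom
    if spec.method == "max_ratio":
        return spec.g_max / denom
    return spec.g_min / denom


def apply_scale(epochs: EpochSeries, scale: float) -> EpochSeries:
    """Multiply the G-values by ``scale``; heart rate is untouched."""
    if scale <= 0:
        raise InvalidInputError("scale must be positive")
    return EpochSeries(
        g_value=epochs.g_value * scale,
        heart_rate_bpm=epochs.heart_rate_bpm.copy(),
        epoch_seconds=epochs.epoch_seconds,
    )
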