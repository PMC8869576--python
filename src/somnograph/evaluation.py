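"""Validation against reference hypnograms and cohort-level statistics.

Epoch-level agreement is summarised by confusion matrices at three
resolutions (wake vs sleep; NREM vs REM; light vs deep vs REM), accuracy
being the diagonal fraction. Night-level summaries follow the standard
actigraphy definitions: total sleep time = 0.5 min per non-WAKE epoch, time
in bed = 0.5 min per epoch, sleep efficiency = 100 * sleep / bed. Cohort
metrics are compared with rank-based tests (rank-sum for two groups,
Kruskal–Wallis for three), and device-vs-reference agreement with MAE,
MAPE, RMSE and Spearman correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Hypnogram, Stage
from .errors import InvalidInputError
from .stats import kruskal_wallis, mann_whitney, spearman

SCHEMES = ("sleep_wake", "nrem_rem", "light_deep_rem")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Epoch-count confusion matrix; rows = reference, columns = predicted."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (len(self.labels), len(self.labels)):
            raise InvalidInputError("counts must be square over the label set")
        if np.any(counts < 0):
            raise InvalidInputError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        """Diagonal fraction, in [0, 1]."""
        if self.total == 0:
            raise InvalidInputError("empty confusion matrix")
        return float(np.trace(self.counts)) / self.total

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * self.accuracy


def accuracy_from_counts(correct: Sequence[int], total: int) -> float:
    """Accuracy (%) from per-class correct counts and the grand total.

    This is the arithmetic a published confusion figure reports: the sum of
    diagonal counts over the total number of epochs.
    """
    correct = np.asarray(correct, dtype=np.int64)
    if total <= 0 or np.any(correct < 0) or correct.sum() > total:
        raise InvalidInputError("need 0 <= sum(correct) <= total, total > 0")
    return 100.0 * float(correct.sum()) / total


def _coarsen(stages: np.ndarray, scheme: str) -> np.ndarray:
    if scheme == "sleep_wake":
        return (stages != int(Stage.WAKE)).astype(int)  # 0 wake, 1 sleep
    if scheme == "nrem_rem":
        return (stages == int(Stage.REM)).astype(int)  # 0 nrem, 1 rem
    # light_deep_rem: 0 light, 1 deep, 2 rem
    out = np.zeros(stages.shape, dtype=int)
    out[stages == int(Stage.DEEP)] = 1
    out[stages == int(Stage.REM)] = 2
    return out


_SCHEME_LABELS = {
    "sleep_wake": ("WAKE", "SLEEP"),
    "nrem_rem": ("NREM", "REM"),
    "light_deep_rem": ("LIGHT", "DEEP", "REM"),
}


def confusion(
    reference: Hypnogram, predicted: Hypnogram, scheme: str = "sleep_wake"
) -> ConfusionMatrix:
    """Confusion matrix of predicted vs reference stages at a resolution.

    The sleep-internal schemes (``nrem_rem``, ``light_deep_rem``) are
    restricted to epochs both hypnograms score as sleep, so wake-detection
    errors do not leak into the sleep-stage comparison.
    """
    if scheme not in SCHEMES:
        raise InvalidInputError(f"scheme must be one of {SCHEMES}")
    if len(reference) != len(predicted):
        raise InvalidInputError("reference and predicted lengths differ")
    ref = reference.stages
    pred = predicted.stages
    if scheme != "sleep_wake":
        keep = (ref != int(Stage.WAKE)) & (pred != int(Stage.WAKE))
        ref, pred = ref[keep], pred[keep]
        if ref.size == 0:
            raise InvalidInputError("no epochs scored as sleep by both hypnograms")
    ref_c = _coarsen(ref, scheme)
    pred_c = _coarsen(pred, scheme)
    labels = _SCHEME_LABELS[scheme]
    k = len(labels)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (ref_c, pred_c), 1)
    return ConfusionMatrix(labels=labels, counts=counts)


@dataclass(frozen=True)
class SleepSummary:
    n_epochs: int
    time_in_bed_min: float
    total_sleep_min: float
    efficiency_pct: float
    pct_light: float
    pct_deep: float
    pct_rem: float
    all_wake: bool = False


def sleep_summary(hypnogram: Hypnogram, epoch_seconds: float = 30.0) -> SleepSummary:
    """Night-level sleep metrics from a 4-stage hypnogram."""
    n = len(hypnogram)
    per_epoch_min = epoch_seconds / 60.0
    tib = n * per_epoch_min
    sleep_epochs = int(np.sum(hypnogram.sleep_mask))
    tst = sleep_epochs * per_epoch_min
    eff = 100.0 * sleep_epochs / n
    if sleep_epochs == 0:
        return SleepSummary(n, tib, 0.0, 0.0, float("nan"), float("nan"),
                            float("nan"), all_wake=True)
    pct = {
        s: 100.0 * int(np.sum(hypnogram.stages == int(s))) / sleep_epochs
        for s in (Stage.LIGHT, Stage.DEEP, Stage.REM)
    }
    return SleepSummary(
        n_epochs=n,
        time_in_bed_min=tib,
        total_sleep_min=tst,
        efficiency_pct=eff,
        pct_light=pct[Stage.LIGHT],
        pct_deep=pct[Stage.DEEP],
        pct_rem=pct[Stage.REM],
    )


def group_compare(
    cohort: pd.DataFrame,
    design: str,
    group_col: str = "group",
    metrics: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-metric rank test across cohort groups.

    ``two_group`` runs the two-sided rank-sum (Mann–Whitney) test,
    ``three_group`` the Kruskal–Wallis test with tie correction. Each group
    needs at least 2 subjects. Returns a table of metric, statistic, p_value.
    """
    if design not in ("two_group", "three_group"):
        raise InvalidInputError("design must be 'two_group' or 'three_group'")
    if group_col not in cohort.columns:
        raise InvalidInputError(f"cohort table lacks a {group_col!r} column")
    groups = {name: sub for name, sub in cohort.groupby(group_col, sort=True)}
    expected = 2 if design == "two_group" else 3
    if len(groups) != expected:
        raise InvalidInputError(f"{design} design needs exactly {expected} groups")
    for name, sub in groups.items():
        if len(sub) < 2:
            raise InvalidInputError(f"group {name!r} has fewer than 2 subjects")
    if metrics is None:
        metrics = [c for c in cohort.columns
                   if c != group_col and pd.api.types.is_numeric_dtype(cohort[c])]
    rows = []
    names = sorted(groups)
    for metric in metrics:
        samples = [groups[n][metric].to_numpy(dtype=float) for n in names]
        if design == "two_group":
            stat, _, p = mann_whitney(samples[0], samples[1])
        else:
            stat, p = kruskal_wallis(*samples)
        rows.append({"metric": metric, "statistic": stat, "p_value": p})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AgreementResult:
    mae: float
    mape_pct: float
    rmse: float
    spearman_rho: float
    spearman_p: float


def agreement(device_metric, reference_metric) -> AgreementResult:
    """Paired agreement between device-derived and reference values.

    MAPE excludes pairs whose reference value is zero. The Spearman p is an
    exact permutation value for n ≤ 9 and a t approximation otherwise.
    """
    dev = np.asarray(device_metric, dtype=float)
    ref = np.asarray(reference_metric, dtype=float)
    if dev.shape != ref.shape:
        raise InvalidInputError("paired metrics must have equal length")
    if dev.size < 3:
        raise InvalidInputError("agreement needs at least 3 pairs")
    err = dev - ref
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    nonzero = ref != 0
    mape = (
        float(np.mean(np.abs(err[nonzero] / ref[nonzero]))) * 100.0
        if np.any(nonzero)
        else float("nan")
    )
    rho, p = spearman(dev, ref)
    return AgreementResult(mae=mae, mape_pct=mape, rmse=rmse,
                           spearman_rho=rho, spearman_p=p)
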