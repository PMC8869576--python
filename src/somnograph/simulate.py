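"""Synthetic overnight recordings with the statistical structure the
staging pipeline assumes.

A night is an epoch-level Markov trajectory over {WAKE, LIGHT, DEEP, REM}
whose self-transition probabilities produce realistic bout durations and a
cyclic light→deep→REM architecture. Conditional on the stage, heart rate is
drawn from a truncated normal with REM > LIGHT > DEEP means (the sympathetic
elevation in REM that the heart-rate clustering exploits) and the activity
G-value from a stage-specific log-normal with wake activity orders of
magnitude above sleep. During REM, with a per-minute burst probability, the
G-value of one epoch in the minute is replaced by a large movement burst —
the abnormal-REM phenotype. Control and Parkinson's profiles differ only in
that burst rate.

Ground-truth REM is suppressed for the first 45 min after sleep onset, so
the onset-lockout post-processing rule is a no-op on truth and an active
correction on corrupted predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EpochSeries, Hypnogram, Stage
from .errors import InvalidInputError

#: default stage-transition matrix, rows/columns ordered WAKE, LIGHT, DEEP, REM
DEFAULT_TRANSITIONS = (
    (0.90, 0.10, 0.00, 0.00),
    (0.02, 0.93, 0.03, 0.02),
    (0.005, 0.03, 0.96, 0.005),
    (0.01, 0.04, 0.00, 0.95),
)

#: transitions for a validation profile with no light-sleep stage and long
#: REM bouts, used to check staging recovery under well-separated conditions
WELL_SEPARATED_TRANSITIONS = (
    (0.90, 0.00, 0.10, 0.00),
    (0.00, 0.00, 1.00, 0.00),
    (0.005, 0.00, 0.975, 0.02),
    (0.01, 0.00, 0.015, 0.975),
)


@dataclass(frozen=True)
class SimProfile:
    """Generator parameters for one cohort's overnight recordings.

    ``hr_mean_bpm``/``hr_sd_bpm`` and ``g_median``/``g_sigma`` are ordered
    (WAKE, LIGHT, DEEP, REM). G medians are in the activity units the
    staging constants assume: quiescent sleep well below one unit (so the
    wake detector scores it as sleep) and wake around twenty. Bursts are
    drawn uniformly from ``burst_range``, whose floor sits just above the
    1500 operating threshold so the abnormal-REM index has signal by
    construction.
    """

    cycle_length_min: float = 90.0
    night_hours: float = 8.0
    epoch_seconds: float = 30.0
    transitions: tuple[tuple[float, ...], ...] = DEFAULT_TRANSITIONS
    hr_mean_bpm: tuple[float, float, float, float] = (72.0, 64.0, 56.0, 74.0)
    hr_sd_bpm: tuple[float, float, float, float] = (3.0, 2.5, 2.0, 2.5)
    g_median: tuple[float, float, float, float] = (20.0, 0.08, 0.02, 0.05)
    g_sigma: tuple[float, float, float, float] = (0.8, 0.5, 0.5, 0.5)
    abnormal_rem_burst_prob: float = 0.0
    burst_range: tuple[float, float] = (1550.0, 4800.0)
    rem_lockout_min: float = 45.0
    seed: int = 0

    def __post_init__(self):
        t = np.asarray(self.transitions, dtype=float)
        if t.shape != (4, 4) or np.any(t < 0) or not np.allclose(t.sum(axis=1), 1.0):
            raise InvalidInputError("transitions must be a 4x4 row-stochastic matrix")
        w, l, d, r = self.hr_mean_bpm
        if not (r > l > d):
            raise InvalidInputError("heart-rate means must order REM > LIGHT > DEEP")
        if not 0.0 <= self.abnormal_rem_burst_prob <= 1.0:
            raise InvalidInputError("abnormal_rem_burst_prob must lie in [0, 1]")
        if self.night_hours <= 0 or self.epoch_seconds <= 0:
            raise InvalidInputError("night_hours and epoch_seconds must be positive")
        if self.burst_range[0] >= self.burst_range[1]:
            raise InvalidInputError("burst_range must be (low, high) with low < high")

    @property
    def n_epochs(self) -> int:
        return int(round(self.night_hours * 3600.0 / self.epoch_seconds))

    @classmethod
    def control(cls, **overrides) -> "SimProfile":
        """Healthy-control profile: rare REM movement bursts (~1.6 %/min)."""
        overrides.setdefault("abnormal_rem_burst_prob", 0.016)
        return cls(**overrides)

    @classmethod
    def parkinsons(cls, **overrides) -> "SimProfile":
        """PD profile: frequent REM movement bursts (~5 %/min)."""
        overrides.setdefault("abnormal_rem_burst_prob", 0.05)
        return cls(**overrides)

    @classmethod
    def well_separated(cls, **overrides) -> "SimProfile":
        """Burst-free validation profile with no light stage and long REM
        bouts, used for staging parameter-recovery checks."""
        overrides.setdefault("transitions", WELL_SEPARATED_TRANSITIONS)
        overrides.setdefault("hr_mean_bpm", (70.0, 64.0, 55.0, 75.0))
        overrides.setdefault("hr_sd_bpm", (3.0, 2.0, 2.0, 2.0))
        return cls(**overrides)


@dataclass(frozen=True)
class SimulatedNight:
    subject_id: str
    group: str
    epochs: EpochSeries
    hypnogram: Hypnogram


def _simulate_stages(profile: SimProfile, rng: np.random.Generator) -> np.ndarray:
    n = profile.n_epochs
    t = np.asarray(profile.transitions, dtype=float)
    lockout = int(round(profile.rem_lockout_min * 60.0 / profile.epoch_seconds))
    stages = np.empty(n, dtype=np.int8)
    state = int(Stage.WAKE)
    onset = None
    for i in range(n):
        stages[i] = state
        if onset is None and state != int(Stage.WAKE):
            onset = i
        row = t[state].copy()
        if onset is None or i < (onset + lockout):
            # REM is locked out until 45 min past sleep onset; its mass is
            # folded into staying put so bout statistics barely change
            row[int(Stage.REM)], extra = 0.0, row[int(Stage.REM)]
            row[state] += extra
        state = int(rng.choice(4, p=row / row.sum()))
    return stages


def simulate_night(
    profile: SimProfile, seed: int | None = None
) -> tuple[EpochSeries, Hypnogram]:
    """One night: epoch series plus ground-truth hypnogram, reproducible
    per seed (defaults to the profile's seed)."""
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    stages = _simulate_stages(profile, rng)
    n = stages.size
    hr_mean = np.asarray(profile.hr_mean_bpm)[stages]
    hr_sd = np.asarray(profile.hr_sd_bpm)[stages]
    hr = np.clip(rng.normal(hr_mean, hr_sd), 20.5, 249.5)
    g_mu = np.log(np.asarray(profile.g_median))[stages]
    g_sig = np.asarray(profile.g_sigma)[stages]
    g = rng.lognormal(mean=g_mu, sigma=g_sig)
    # movement bursts: one Bernoulli draw per REM minute (epoch pair)
    if profile.abnormal_rem_burst_prob > 0:
        rem = int(Stage.REM)
        i = 0
        while i < n:
            if stages[i] != rem:
                i += 1
                continue
            j = i
            while j < n and stages[j] == rem:
                j += 1
            for a in range(i, j, 2):
                if rng.random() < profile.abnormal_rem_burst_prob:
                    g[a] = rng.uniform(*profile.burst_range)
            i = j
    epochs = EpochSeries(g_value=g, heart_rate_bpm=hr,
                         epoch_seconds=profile.epoch_seconds)
    return epochs, Hypnogram(stages, provenance="reference")


def simulate_cohort(
    n_control: int,
    n_pd: int,
    control_profile: SimProfile | None = None,
    pd_profile: SimProfile | None = None,
    seed: int = 0,
) -> list[SimulatedNight]:
    """Independent nights for a two-group cohort with per-subject seeds."""
    if n_control < 1 or n_pd < 1:
        raise InvalidInputError("cohort sizes must be >= 1")
    control_profile = control_profile or SimProfile.control()
    pd_profile = pd_profile or SimProfile.parkinsons()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_control + n_pd)
    nights = []
    for k in range(n_control + n_pd):
        group = "control" if k < n_control else "pd"
        profile = control_profile if group == "control" else pd_profile
        rng_seed = int(children[k].generate_state(1)[0] % (2**31 - 1))
        epochs, hyp = simulate_night(profile, seed=rng_seed)
        nights.append(
            SimulatedNight(subject_id=f"{group}_{k:03d}", group=group,
                           epochs=epochs, hypnogram=hyp)
        )
    return nights
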