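# Methods

This note records the model behind `somnograph`, the parameters that
matter, the design decisions taken where the published description is
silent or inconsistent, and what the synthetic-data tests do and do not
demonstrate.

## Representation

The atomic unit is the non-overlapping 30-second epoch. A night is an
`EpochSeries` — per-epoch activity magnitude (*G-value*, device activity
units, ≥ 0) and mean heart rate (bpm, plausibility window 20–250) — plus a
`Hypnogram` of labels from {WAKE, LIGHT, DEEP, REM}. Coarser views (NREM =
LIGHT∪DEEP, SLEEP = non-WAKE) are always derived, never stored.

### From raw streams to epochs

The published pipeline never states how the per-epoch G-value is derived
from the 250-Hz accelerometer stream. Our convention: the G-value is the
maximum of the dynamic acceleration magnitude |‖a‖ − 1 g| within the epoch,
reported in milli-g; the aggregator is configurable (`max`, `mean`, `sum`)
for devices that report integrated counts. Epochs start at the first
sample's timestamp (no clock snapping) and a trailing partial window is
dropped, so the epoch count is ⌊duration / 30 s⌋.

Beat-to-beat (RR) intervals are cleaned to the physiological window
(200, 4000) ms, averaged per epoch, and converted as 60000 / mean-RR. An
epoch without beats takes the value of the nearest epoch with beats (ties
toward the earlier epoch) — the heart-rate clustering cannot accept missing
values, and nearest-neighbour filling is the least-structured imputation at
this resolution. Every fill is reported through a warning.

## The staging pipeline

### Sleep/wake (Cole–Kripke)

`D_t = P · Σ_{k=−4..+2} W_k · A_{t+k}`, weights
(W₋₄..W₊₂) = (50, 30, 14, 28, 121, 8, 50), `P = 0.01076`; wake iff
`D_t ≥ 1`. The published weight list contains a typographical duplicate
("W₋₁" printed twice, 28 and 8); the equation has exactly the offsets
−4..+2, so the second entry is read as W₊₁ = 8. Window positions outside
the record contribute zero activity — standard actigraphy practice for
boundary epochs. `P` is a fitted constant of the source cohort and is
exposed in `StagingConfig`, not re-fitted here (the cohort data are not
public).

### Light/deep scoring

The published rule gives per-bin score increments (+1 below 40; −2, −3,
−5, −10, −20 up to 600) but not how the score maps to stages, whether it
is cumulative, or the increment above 600. Our reading: a running
cumulative score over the sleep epochs in time order, starting at 0 and
clamped below at 0; an epoch is DEEP iff its post-update score exceeds
`deep_score_threshold` (default 0); G ≥ 600 extends the last increment
(−20). The clamp prevents one long movement bout from suppressing deep
sleep for the rest of the night; the threshold is configurable because this
mapping is our convention, not an established one.

### REM from heart rate

Two-cluster k-means is fitted per subject-night on the heart rate of the
DEEP epochs; the higher-heart-rate cluster is relabelled REM. This
exploits the sympathetic elevation of heart rate in REM relative to
slow-wave sleep, and per-night fitting absorbs between-subject baseline
differences. Clustering on heart rate (bpm) versus RR interval (ms) is a
monotone reparameterisation that can nevertheless move cluster boundaries;
bpm is the default and `cluster_on = "rr"` is exposed.

Numerical choices for the 1-D k-means: Lloyd's iteration (assign to the
nearer centroid, ties to the lower-valued centroid; update subset means;
stop at an assignment fixed point or `kmeans_max_iter`). Because the
update is deterministic, a single pass with unchanged assignments is a
fixed point, which satisfies any stability patience — the conventional
100-iteration patience is therefore reported as converged at the first
fixed point. Initialisation uses a deterministic portfolio: a seeded draw
of two distinct observed values, the (min, max) pair, and the subset means
of the exact optimal contiguous split (prefix-sum scan); the run with the
lowest within-cluster sum of squares is kept. A single random start can
stall on a suboptimal Lloyd fixed point even in one dimension (e.g.
{0, 2.1, 3, 4} started from (2.1, 4)); the portfolio guarantees the global
optimum, which the test suite verifies against an independent exhaustive
oracle. Degenerate input (constant heart rate over DEEP) skips the split
and flags the night rather than fabricating clusters.

### REM cleanup rules

Applied once each, in order, on the 4-label hypnogram:

1. REM within the first 45 min after sleep onset (first non-WAKE epoch) is
   demoted — REM virtually never occurs that early, so early "REM" is
   treated as a clustering error.
2. Separated REM segments shorter than 5 min are demoted.
3. Non-REM runs of ≤ 3 min flanked by REM on both sides are promoted to
   REM, provided the run contains no WAKE (we read "non-REM" as
   sleep-internal; wake bouts are preserved).

Demotions target DEEP because those epochs were DEEP before the heart-rate
split, keeping the relabel history consistent. One pass is a fixed point:
rule 1 leaves no REM before onset + 45 min and promotions only occur
between surviving (later) REM runs; after rules 2–3 every REM run is ≥ 5
min and every qualifying gap is already merged. Idempotence is
regression-tested on 1000 random hypnograms.

## Cross-device scaling

Activity ranges differ between wrist sensors, so recordings from another
device are mapped into the reference range by one multiplicative factor:
range-ratio (Gmax−Gmin)/(Gdmax−Gdmin), max-ratio Gmax/Gdmax, or min-ratio
Gmin/Gdmin (default, the best-performing variant in the source validation).
Extrema default to the whole recording per subject-night — the smallest
self-contained unit — and can be supplied explicitly for pooled
calibration. The min-ratio fit-then-apply identity (source minimum maps
exactly onto the reference floor) is asserted in the tests.

## Abnormal-REM index and threshold selection

`% abnormal REM = 100 · n / T`, `n` = REM minutes with G above the
threshold, `T` = total REM minutes. The pipeline is epoch-based while the
index counts minutes, so within each contiguous REM run consecutive epoch
pairs form minutes (a trailing single epoch counts as one minute),
aggregated by the max G of the minute (`mean` is exposed). A night without
REM reports 0 % with an explicit flag instead of an undefined division.
The index is non-increasing in the threshold.

The threshold sweep evaluates candidates 1200…4500 (step 300; the
operating default is 1500): per candidate, each subject is summarised —
abnormal REM minutes by default; the percentage, or the median
suprathreshold minute-G, are exposed because the published description is
ambiguous about the swept statistic — and the cohorts compared by a
two-sided Mann–Whitney test. The chosen threshold minimises p, ties
resolved toward the smaller threshold (deterministic, and the more
sensitive choice).

## Statistics

Two-group comparisons use the rank-sum (Mann–Whitney) test: the cohorts
are independent samples, for which a signed-rank pairing is undefined.
Exact null distributions are used for tie-free samples of combined n ≤ 20,
otherwise the tie-corrected normal approximation. Three-group comparisons
use Kruskal–Wallis with tie correction (H = 0, p = 1 on fully tied input).
Agreement metrics are the standard MAE, MAPE (pairs with a zero reference
are excluded), RMSE and Spearman's ρ, whose p-value is an exact
permutation value for n ≤ 9 and the t approximation above. Exactness of
the small-sample rank tests is verified in the suite against brute-force
enumeration over all rank assignments.

Confusion matrices are reported at three resolutions; the sleep-internal
schemes (NREM/REM and light/deep/REM) are restricted to epochs both
hypnograms score as sleep, so wake-detection errors do not contaminate the
sleep-stage comparison. Night summaries: total sleep time = 0.5 min per
non-WAKE epoch, time in bed = 0.5 min per epoch, sleep efficiency =
100 · sleep/bed, stage percentages relative to sleep epochs (they sum to
100 exactly).

## The activity-scale tension, and how the index is evaluated

The published constants are internally inconsistent about the scale of the
activity score. With `P = 0.01076` and `W₀ = 121`, an epoch is scored wake
whenever its own G-value reaches `1/(P·W₀) ≈ 0.77` — yet the light/deep
bins span 40–600 and the RBD thresholds 1200–4500 on the same quantity.
Two consequences follow mathematically:

- For the wake detector to function at all, sleep-time activity must sit
  in the sub-unit regime, in which case every sleep epoch falls in the
  lowest score bin and the scorer alone can only produce DEEP (LIGHT
  emerges only through the cleanup rules or a different score threshold).
- A movement burst above any RBD threshold forces `D ≥ 1` over seven
  consecutive epochs (the burst weighted by 50, 8, 121, 28, 14, 30, 50 at
  offsets −2…+4; even the smallest weight needs only G ≈ 12), i.e. 3.5 min
  of wake — longer than the 3-min merge limit of cleanup rule 3. A staged
  hypnogram therefore *cannot* carry a REM label on a suprathreshold
  epoch, and the abnormal-REM index computed on staged output is
  identically zero. The suite asserts this structural property directly.

The index is accordingly scored against a reference hypnogram (the
simulator's ground truth, or PSG labels for real data): REM periods are
established by the reference, and the G-series supplies the movement
signal. This is also the clinically coherent reading — the movement that
defines RBD is precisely what corrupts a movement-based stage label, so
the stage context must come from a source the movement cannot erase. The
cohort-level recovery checks (group separation and threshold selection)
are stated and tested on this basis; staging quality is assessed
separately, on burst-free nights.

## The synthetic night generator

`SimProfile` defines an epoch-level Markov chain over the four stages whose
self-transition probabilities set bout durations (defaults give roughly
40 % light, 30 % deep, 19 % REM, 11 % wake of the night and a cyclic
light→deep→REM progression); REM transitions are suppressed until 45 min
after sleep onset so the truth respects the onset-lockout rule by
construction. Stage-conditional heart rate is truncated normal with means
WAKE 72, LIGHT 64, DEEP 56, REM 74 bpm (REM > LIGHT > DEEP enforced);
activity is log-normal with sleep medians in the sub-unit regime the wake
detector requires (DEEP 0.02, REM 0.05, LIGHT 0.08) and wake two orders
larger (median 20). During REM, each minute independently carries a
movement burst with probability 0.016 (control profile) or 0.05
(Parkinson's profile), drawn uniformly from 1550–4800 — just above the
1500 operating threshold, so the index has signal by construction. The
burst rates were chosen once to match the reported abnormal-REM
percentages (≈ 1.6 % in controls; ≈ 4–6 % in unmedicated patients); the
default two-group cohort is 18 controls vs 20 patients. A separate
burst-free `well_separated` profile (no light stage, long REM bouts,
wider heart-rate separation) is used to measure staging recovery;
cumulative-score staging reaches ≥ 90 % epoch agreement with truth there.

What the generator does *not* emulate: within-stage autocorrelation of
heart rate and activity, circadian drift, heart-rate arousals decoupled
from movement, device artefacts (gaps, clipping, wear errors), and any
light-sleep signature the cumulative scorer could detect (see the scale
tension above). Passing tests therefore demonstrate algorithmic
correctness and cohort-level recovery under the model's own assumptions,
not clinical performance on real recordings.

## Problem sizes and tolerances

Simulated nights are 8 h (960 epochs); cohort checks use 18 + 20 nights;
clustering is verified on 250 random instances of ≤ 12 points; rank-test
exactness on all group-size pairs up to 8 (≤ 12,870 enumerated
assignments); idempotence on 1000 random hypnograms. Published
confusion-count arithmetic is checked at two decimals; one published
three-stage accuracy is internally inconsistent with its own counts by one
unit in the last digit (64.0139…% vs a printed 64.02 %), so agreement
there is asserted at the printed precision (±0.01). Floating-point CSV
round-trips are exact (values are parsed with the exact decimal parser).

## Known limitations

- `P` and the score bins are constants of the source device; applying the
  pipeline to another sensor requires the rescaling module and possibly a
  recalibrated `P`.
- The cumulative light/deep score is our reading of an under-specified
  rule; with the published constants it yields little or no LIGHT (see the
  scale tension).
- The index requires a reference hypnogram for its REM context; a fully
  self-contained staged-output index is structurally zero under the
  published constants.
- Exact rank tests switch to asymptotics in the presence of ties or larger
  samples; p-values near the switch boundary can differ in the third
  decimal from fully exact values.
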