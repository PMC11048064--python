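# Methods

This note documents the models, conventions and numerical choices behind
`mobiseg`: how the detectors work and why their thresholds are what they
are, what the synthetic-data generator does and does not emulate, how the
statistics layer is defined, and the known limitations of each.

## Signal model and conventions

A trial is a synchronized set of eight IMU streams (feet, shanks, thighs,
sacrum, sternum), each carrying 3-axis angular velocity (deg/s) and linear
acceleration (m/s²) at a common sampling rate (100 Hz by default). All
detectors operate on *resultant* (Euclidean-magnitude) channels, which are
orientation-free: they are invariant to sensor mounting rotation, at the
cost of discarding movement direction. Times are seconds from recording
start; sample `i` maps to `t = i / fs`; units are never converted
implicitly. Missing or non-finite samples are a hard error — the package
does not impute; a trial that cannot be segmented is reported as failed in
the run manifest for manual review rather than silently repaired.

All signals are conditioned with a 4th-order low-pass Butterworth filter at
5 Hz. Filtering is **zero-phase** (forward–backward) by default: event
*times* are the product of this package, and a causal filter would bias
every detected event late by the group delay. A causal option
(`FilterSpec(zero_phase=False)`) exists for streaming-style use. Note that
forward–backward application squares the magnitude response, so the
effective attenuation at frequency f is `1 / (1 + r^8)` with
`r = tan(πf/fs) / tan(πf_c/fs)` (the bilinear-warped frequency ratio).

### Movement onset/offset

`onset_offset` thresholds a series against its own quiescent baseline: the
first `baseline_window_s` (default 0.5 s) provide mean and SD; the
threshold is `mean + max(k·SD, floor)` with `k = 3` and an absolute floor
(3 deg/s for gyroscope resultants) so a noise-free baseline cannot produce
a zero threshold. An excursion counts only if sustained for ≥ 100 ms,
rejecting isolated spikes. These constants are configuration, not claims:
the underlying protocol describes onset only qualitatively ("a significant
rise"), so the quantitative rule is a package choice, chosen to be the
textbook baseline-referenced rule in movement science.

### Convex-bump edges (`bump_bounds`)

Chair transfers and turns appear as smooth convex bumps in resultant
angular velocity. Their edges are estimated from the **width at half
amplitude**: for a raised-cosine bump the two half-amplitude crossings sit
at ¼ and ¾ of its duration, so `onset = t_left − w/2`,
`end = t_right + w/2` with `w = t_right − t_left`. Both crossings lie on
the steepest part of the bump, which makes the estimator robust to
additive noise; thresholding near the base (where the slope vanishes) or
mirroring about the apex (which is flat, hence poorly localized) were both
tried and produce event errors several times larger at realistic noise.
The estimator is exact for raised-cosine bumps and is accurate for any
approximately symmetric unimodal bump.

## Detectors

### Timed Up and Go

Six events partition the test into five sections. The detector uses three
angular-velocity resultants (trunk, both thighs) and the two foot
acceleration resultants:

- **T1 / T6** — earliest refined onset / latest refined offset among
  trunk and thighs (`onset_offset`, refined to the adjacent bump edge).
  The trunk's own settling edge at test end merges the final turn bump's
  fall with the drop of the walking baseline, so the trunk's T6 candidate
  is taken as the *end of the second turn bump* instead, whose
  half-amplitude crossings sit well above that drop.
- **Turn bumps** — trunk peaks ≥ 50 % of the trial maximum, separated by
  ≥ 2 s; exactly two are expected (turn-at-cone, turn-and-sit). Fewer is a
  segmentation failure (the case the underlying protocol resolved by
  manual adjustment); more than two keeps the two most prominent.
- **T3 / T4 / T5** — edges of the two turn bumps against the walking
  baseline (estimated as the median of the trunk resultant over the active
  interval, which walking dominates). T3 is additionally snapped to the
  last foot-acceleration step peak within [−0.45 s, +0.10 s] of the bump
  onset — the foot plant that ends the final stride and initiates the
  turn.
- **T2** — the first step peak after T1 minus a configurable
  gait-initiation latency (0.10 s): walking is deemed to start one
  weight-transfer latency before the first detectable foot-contact peak.
  The protocol gives no rule here; generator and detector share this
  convention explicitly rather than hiding it in either side.

Step peaks use an adaptive threshold — 30 % of the 95th percentile of the
windowed signal, floored at 1 m/s² — because fixed thresholds fail across
noise levels and subjects; peaks on one foot closer than 250 ms are
suppressed and near-coincident peaks across feet are merged. Step counts
for the cadence features are taken strictly inside the walking windows
(T2, T3) and (T4, T5), widened by a 50 ms timing-tolerance slack so a foot
plant lying exactly on a section boundary is not lost to a few-millisecond
event error (the slack is far below the minimum step separation, so no
neighbouring step can be double-counted). Cadence is defined as
`60·steps / section time`, so the identity `cadence · time = 60 · steps`
holds by construction, as does `Σ section times = total time`.

### Sit-to-stand

Each sit–stand–sit cycle produces two convex lobes in thigh resultant
angular velocity. Detection runs on the left/right *average* by default
(suppressing unilateral noise — relevant for hemiparetic movement; single
sides are a config option): threshold crossings above the quiescent
baseline are merged across dips shorter than 80 ms, runs shorter than
300 ms are discarded, and surviving lobes' edges are refined with
`bump_bounds`. Exactly `2·n_cycles` lobes are required; consecutive lobes
are paired in order (first = rising, second = sitting down) with a maximum
intra-cycle gap of 3 s. Total time spans the first lobe's start to the
last lobe's end — including inter-cycle rests, since the protocol's
"total time" is the duration of the whole activity — and mean cycle time
is total/n by definition. RMS features are computed over that full active
interval (not per cycle) on the filtered resultants of sternum, sacrum and
both thighs.

### 10 m walk

Each stride yields two shank-acceleration peaks: toe-off at swing onset
and heel strike at swing end. Per side, peaks above the adaptive
prominence threshold are partitioned into strides using the bimodal
inter-peak gap distribution (within-stride TO→HS gaps are shorter than
between-stride HS→TO gaps whenever swing occupies less than half the
stride; the split point is the midpoint of the two gap-cluster medians).
The first peak of each pair is labelled TO, the second HS; labelling by
amplitude (HS taller) is a config alternative. Unpaired peaks are a
segmentation failure; fewer than two strides on a side is an
insufficient-gait error. Peak times are refined by parabolic
interpolation, giving sub-sample (≈ millisecond) accuracy on clean
signals.

Features: walk time spans the first to the last detected event (the
protocol does not state its endpoints; this is the package's definition);
steps = total heel strikes over both sides; cadence and gait speed follow
their exact identities. Stride duration averages same-side HS→HS
intervals; the swing fraction of a stride is (HS − preceding TO)/stride
duration, so swing + stance = 1 per stride by construction. **Single
support** is defined here as the mean fraction of a stride during which
exactly one foot is in ground contact, computed from the bilateral
interleaving with stance = HS → next same-side TO; for symmetric gait this
equals `2 × swing fraction` (≈ 0.76 at swing 0.38). The reference tables
print "single support ≈ 0.60", which exceeds the physiological
single-limb-support fraction and is not reproducible under any standard
definition we could construct; the package documents and uses its own
definition consistently (generator and detector agree) rather than
guessing the printed one. Similarly, the printed walk-time, step-count,
cadence and gait-speed cells are not jointly realizable by a single
constant-stride model (they imply different measurement windows), so the
walk-related group contrasts are computed by cell-mean arithmetic rather
than asserted through signal simulation.

## Synthetic data

The generator produces exactly the signal features the detectors consume,
with exact ground truth:

- walking: per-step Gaussian acceleration transients (σ = 25 ms, ≈ 60 ms
  at half maximum) on a 9.81 m/s² gravity-magnitude baseline; in walk
  trials a TO peak (4 m/s²) and HS peak (6 m/s²) per stride per side,
  right offset by half a stride;
- turning: raised-cosine trunk angular-velocity bumps (peak 100 deg/s)
  riding on a 10 deg/s walking baseline;
- chair transfers: raised-cosine thigh lobes (60 deg/s) with scaled trunk
  and pelvis copies;
- i.i.d. Gaussian sensor noise per axis (defaults 1.5 deg/s and
  0.15 m/s²).

It does **not** model per-axis realism, orientation dynamics, stride-to-
stride variability within a trial, asymmetric gait, double-support
dynamics or soft-tissue artefacts. Passing round-trip tests therefore
demonstrates that the detectors correctly implement their stated rules and
are robust to additive noise at realistic amplitudes — not that they are
validated on real patient data.

The sit-to-stand generator can rescale each channel so its noiseless RMS
over the active interval matches a target; the reference tables print
trunk RMS values around 1 deg/s, far below plausible trunk motion, so the
cohort uses those cells multiplied by a configurable scale (default 15).
Percent contrasts between cells are invariant to this factor, which is the
quantity the cohort reproduces.

### Cohort generation

A cohort draws each feature-driving parameter per subject and condition
from its group × load cell `(mean, SD)`, with a shared subject-level
component (weight 0.7) giving the repeated-measures correlation, truncated
at ±3 SD and clipped at physiologic bounds. Two deliberate choices:

- **Empirical centering (default).** Standardized draws are centred within
  each cell before scaling, so the realized cell means equal the specified
  means exactly (the approach of `MASS::mvrnorm(empirical=TRUE)`). The
  cohort's purpose is to present *known* cell-level conditions to the
  pipeline; without centering, a 100-per-group cohort carries ±1–2 % cell-
  mean sampling error that would be attributed to the pipeline. Plain
  i.i.d. sampling is available via `empirical=False` and is what the
  large-n convergence test uses.
- **Cadence clamping.** Step counts and section durations are drawn
  marginally, so rare joint draws imply impossible cadences; the step
  count of a generated TUG trial is clamped into the feasible band
  (0.31–2.99 steps/s) for its drawn duration. Out-of-band parameter
  combinations passed directly to the trial generators still raise.

## Statistics

Each of the 25 features is analysed with a two-way mixed-design ANOVA:
between-subject factor group, within-subject factor cognitive load, plus
their interaction. With only two within levels, sphericity holds trivially
and no correction is applied. The sums of squares are the observation-
weighted (sequential) decomposition, which is exactly additive —
`SS_total = SS_group + SS_subjects(group) + SS_load + SS_interaction +
SS_within-error` — for any group sizes, and coincides with the standard
mixed-ANOVA table for balanced groups (verified against pingouin to 1e-8,
balanced and unbalanced, and against a brute-force sequential projection
oracle in the tests). The group effect is tested against subjects-within-
groups; load and interaction against the within-subject error. Partial η²
is `SS_effect / (SS_effect + SS_error-of-that-stratum)`, classed small
below 0.06, medium from 0.06 to 0.14, large above 0.14. One printed label
in the reference report (0.107 marked large) contradicts those thresholds;
the classifier follows the stated rule (medium). No multiple-testing
correction is applied across features, mirroring the reference analysis;
Shapiro–Wilk screening per design cell is reported, never used to drop
data, and outliers are surfaced rather than removed.

Group contrasts are percent differences of stroke vs control cell means.
The default pools each group over both load conditions —
`100·(mean(stroke cells) − mean(control cells)) / mean(control cells)` —
because that arithmetic reproduces the headline percentages computable
from the reference cell means (23 % total TUG time, 20 % walk-to-cone,
15 % turn, 29 % turn-and-sit, 21 % walk time, −20 % trunk RMS); ST-only
and DT-only variants are provided (DT-only reproduces the −18 % gait-speed
figure). Two further published percentages (a 20 % ST→DT increase in TUG
time and a 31 % turn-time increase) are not reproducible from the cell
means under any of these conventions; the conventions are exposed but no
claim is made about which one produced those numbers. Dual-task cost is
`100·(DT − ST)/ST` per subject, averaged across subjects.

## Problem sizes and numerical tolerances

The test-suite and acceptance-script simulations use 200 trials per
detector check, 1000 replicates for null calibration at 20 subjects per
group, and a 100-per-group TUG+STS cohort for end-to-end recovery — sizes
at which binomial/sampling uncertainty is well below the asserted margins.
Event-recovery margins are ±50 ms (TUG, STS) and ±30 ms (gait) at default
noise; algebraic identities (section partition, cadence/speed identities,
SS conservation) are asserted to 1e-8 or tighter. Exact arithmetic
examples are asserted at printed precision.

## Known limitations

- Detectors assume one trial per recording (a single TUG sequence, one
  walking bout, one block of STS repetitions) and a quiescent baseline at
  the start of the recording.
- The gait stride-partitioning heuristic requires the swing phase to
  occupy less than half of the stride (true of normal and hemiparetic
  overground gait, not of running).
- Turn detection expects the two turn bumps to dominate trunk angular
  velocity; pathologies producing comparable trunk spikes during straight
  walking would need per-trial threshold configuration.
- The ANOVA layer requires complete ST/DT pairs per subject and feature;
  incomplete subjects are excluded from that feature's model (and kept in
  the feature table).
- Statsmodels-style Model/Results objects are used where a model is
  actually fitted (the statistics layer); the segmentation side of the
  package is a signal-processing pipeline and keeps a functional API.
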