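# Methods

This note documents the models, conventions and numerical choices
behind `frtkin`, in the spirit of a statistical package's methods
appendix: what is computed, under which assumptions, and what the
synthetic-data tests do and do not demonstrate.

## Signal model and preprocessing

A trial is a pair of tri-axial recordings (trunk at T7, lumbar at
L5–S1) at a nominal 32 Hz: accelerometer (m/s²), optionally gyroscope
(°/s) and attitude (pitch/roll/yaw, °).  All analysis happens on the
**pitch displacement series**: the forward-lean angle relative to the
held starting posture.

- **Resampling.** Raw logs may have jittered timestamps; every channel
  is linearly interpolated onto a uniform grid spanning the recorded
  range (`resample_uniform`).  Linear interpolation is exact on affine
  segments and adequate for a quasi-static reach sampled at 32 Hz.
- **Pitch source.** When the recorder app provides attitude channels
  they are used directly and unsmoothed — this keeps clean recordings
  bit-faithful and makes noise-free event recovery exact.  Without
  attitude, pitch is estimated from the gravity direction in the
  accelerometer: each axis is low-pass filtered (4th-order zero-phase
  Butterworth, default cutoff 2 Hz) and pitch is
  `atan2(a_fwd, hypot(a_lat, a_vert))` under a named axis convention
  (`flat_back`: device flat on the back, long axis head-to-foot).  A
  2 Hz cutoff is far above the movement band (a reach cycle lasts
  ~11–23 s, fundamental ≈ 0.06 Hz) and far below the sensor noise
  band.  This gravity-tilt estimate assumes negligible linear
  acceleration relative to g, which holds for the slow controlled
  reach; no orientation fusion (quaternion/Kalman) is attempted.
- **Baseline.** The starting posture is the mean pitch over an initial
  quiet window (default 0.5 s) and is subtracted, so a forward reach is
  a positive excursion from ≈ 0°.  Forward lean positive by
  convention; a flag flips the sign for other mountings.

## Event detection

Three events partition one reach: A (onset), B (maximum angular
displacement), C (return).  On the pitch series:

- **B** is the first sample attaining the global maximum.
- **A** is the last sample before B at or below
  `onset_fraction × peak` (default 5% — relative thresholds transfer
  across subjects whose amplitudes differ several-fold).
- **C** is the first sample after B at or below that threshold that
  stays below it for `hold_s` (default 0.25 s), so a momentary noise
  dip during the return does not end the movement; a below-threshold
  run that reaches the end of the record counts as sustained.  A
  recording that ends mid-return raises an error unless `allow_clamp`
  pins C to the last sample.
- `min_peak_deg` (default 3°) rejects recordings with no discernible
  movement; the smallest realistic interval displacements in this
  population are ≈ 4–6°.
- Multi-repetition recordings are split into maximal excursions above
  the onset threshold and the excursion with the largest peak is
  analysed (`select_widest`), ties going to the earliest — the
  convention of scoring the widest reach.

**Noisy recordings.** Attitude channels carry wide-band noise that an
argmax/threshold detector sees directly.  The recommended workflow
(`segment_reach`) is two-stage:

1. smooth the pitch series with a zero-phase Butterworth at
   `EVENT_CUTOFF_HZ = 0.3 Hz` and detect events.  0.3 Hz is ~1.5× the
   movement band edge; empirically (on the generator's nominal trial
   with 0.5° attitude noise) it minimises event-timing error — higher
   cutoffs leave too much noise for peak localisation, lower ones
   distort the onset corners;
2. **re-baseline and re-detect**: with approximate events known, every
   sample up to 0.25 × the adjacent interval duration before A and
   after C is rest; their mean re-references the series and detection
   runs once more.  The short initial quiet window's sampling noise
   (σ ≈ 0.12° at 0.5 s) otherwise propagates into every threshold
   crossing; the refined baseline uses several seconds of rest.  The
   fractional margin is chosen because the pre-threshold part of a
   smooth rise occupies ~0.17 of the measured A–B interval.  On clean
   series both stages are exact no-ops.

With this workflow, 97% of simulated nominal trials with 0.5° attitude
noise localise all three events within 0.25 s of ground truth; on
noise-free trials recovery is exact to one sample period.  A flat
plateau at the peak makes "the instant of maximum displacement"
set-valued, so peak-timing error is measured as the distance to that
interval.

## Kinematic variables

For each interval I ∈ {A_B, B_C, A_C}: duration from the event times;
displacement as the absolute pitch difference between the interval's
endpoints (reported as positive magnitudes); speed = displacement /
duration; acceleration = speed / duration (= displacement/duration²).
The acceleration convention is the per-interval mean-ratio one — it is
the convention under which the printed reference tables' speed and
acceleration means are mutually consistent — rather than a second
derivative of the trajectory.  A_C durations and displacements are
exact sums of the sub-intervals, so the additivity identities hold to
the last bit, and `speed × duration = displacement`,
`acceleration × duration = speed` hold to 1e-12 per interval.  Ratios
are computed per trial and aggregated afterwards (a mean of ratios,
not a ratio of means), the only reading consistent at subject level.

Per-axis summaries over [t_A, t_C]: angular velocity from the
gyroscope when present, else the finite-difference derivative of the
attitude angles; linear acceleration from the accelerometer; per-axis
max/min/mean, combined across axes by root-sum-of-squares into the
resultants.  Per-axis displacement (for the resultant displacement) is
the attitude range per axis, or the range of the integrated gyroscope
when attitude is absent.

Human-facing tables round to 2 decimals (kinematics) or 3 decimals
(ICC), **half away from zero** — bankers' rounding would print 0.155
as 0.15.  Machine outputs keep full precision.

The reach distance in cm is carried as metadata only; no regression
from angular amplitude to distance is attempted.

## Reliability and comparisons

- **Normality**: one-sample Kolmogorov–Smirnov against a normal with
  estimated mean/SD, p-values with the Lilliefors correction
  (statsmodels); the naive KS p-value is anti-conservative with
  estimated parameters.  Note the test's power against a uniform
  alternative at n = 100 is only ≈ 0.55 — its statistic hovers near
  the 0.0886 critical value — so single-sample rejections are not
  guaranteed even for clearly non-normal data.
- **Paired comparison** (`paired_compare`): normality of the paired
  differences gates a paired Student t (not rejected at α) against a
  Wilcoxon signed-rank (zeros dropped; exact null distribution up to
  n = 25 when ranks are untied, normal approximation with continuity
  correction otherwise).  Measured type-I error on 1000 paired-null
  simulations at n = 20 sits within the 99% binomial band of 0.05.
- **ICC**: from the two-way (subjects × columns) ANOVA mean squares.
  Default ICC(2,1) — two-way random effects, absolute agreement,
  single measures — because absolute agreement is the conservative
  standard for method-reliability claims; ICC(3,1) (consistency, which
  forgives constant rater offsets) by flag, and the form label always
  accompanies the estimate.  95% CIs use the McGraw–Wong F-distribution
  bounds (Satterthwaite df for the rater+error composite).  Estimates
  are verified against an independent double-loop variance-components
  computation and against `pingouin.intraclass_corr` in the tests.
  The single-measures estimator is moderately biased downward at small
  designs (≈ −0.02…−0.04 at 10 subjects × 3 columns), which the
  recovery tests account for.
- **Bands**: very low < .30 ≤ low < .50 ≤ moderate < .70 ≤ high
  < .90 ≤ very high, closed on the printed boundaries; negative
  estimates are "very low".

Intraobserver grids are one observer's readings across repetitions;
interobserver grids are all observers' readings of one repetition.
The reliability of indirect variables is not computed separately — it
is determined by the direct measures they are ratios of.

## Synthetic data generator

`simulate_trial` builds one trial: the pitch trajectory is a
raised-cosine rise of duration `rise_s` to the trial amplitude, a
brief plateau (default 0.3 s — a reach is held only momentarily), and
a raised-cosine return — continuous velocity and bounded acceleration,
matching a smooth controlled movement.  Channels are generated
consistently: attitude = true pitch + white noise (default SD 0.5°);
accelerometer = gravity rotated through the pitch + white noise
(0.05 m/s²); gyroscope = the analytic pitch rate + white noise
(0.5 °/s).  The lumbar device shares the trial's timing with amplitude
attenuated by 0.87 (the two placements record one underlying movement;
the attenuation ratio is a free parameter, not a claim about anatomy).

Scale defaults mirror the instrumented-reach setting the pipeline
targets: 7 subjects × 3 repetitions × 2 observers at 32 Hz; trunk
amplitude 12.6 ± 5.2° between subjects; rise 8.8 ± 1.3 s and return
7.2 ± 2.7 s; reach distance 13.15 ± 2.49 cm.  Subject-level
amplitudes and phase durations are drawn from **lognormals
moment-matched** to those means/SDs: they are positive and
right-skewed by nature, and a matched normal would put ~3% of subjects
below the detection floor.  Trial effects are additive Gaussian
(amplitude SD 1.5°, timing SD 0.3 s — plausible trial-to-trial
variation for a repeated clinical test); an observer reading perturbs
the three marked instants (SD 0.25 s) and levels (SD 0.5°) and derives
durations/displacements from the marks, so one observer's readings are
internally additive.

Ground truth records the detector-consistent analytic events: the 5%
threshold crossings of the raised-cosine phases and the first instant
at the peak (with the plateau window for set-valued peak timing).  The
implied true ICC of each variable follows from the variance components
(between / (between + within) for the repetition design; the trial
effect joins "between" for the observer design).  All randomness flows
from one root seed through named substreams (subjects, trials,
observers, sensor noise), so toggling one source never reshuffles the
others.

**What the generator does not emulate:** anticipatory postural sway
before onset, asymmetric or aborted reaches, sensor bias drift and
axis misalignment, magnetometer effects, and any trunk–lumbar timing
decoupling.  Passing recovery tests therefore demonstrates correctness
of the pipeline's conventions and its robustness to wide-band sensor
noise — not robustness to every artefact of real clinical recordings.

## Problem sizes and determinism

The test-suite and acceptance experiments use: 200 noisy trials for
segmentation recovery; 2000 simulated cohorts per true-ICC level for
parameter recovery (so the Monte-Carlo error of the mean, ≈ 0.004, is
small against the 0.05 accuracy requirement); 1000 paired-null
simulations for type-I calibration.  All are seeded; the CLI's
machine-readable outputs are byte-identical for identical config and
seed.

## Known limitations

- The gravity-tilt pitch estimate degrades if the reach involves
  appreciable linear acceleration or roll; the attitude channel is
  preferred when present.
- Threshold-based onset/return definitions systematically exclude the
  sub-threshold tails of the movement (~14% of each phase duration at
  the 5% threshold); measured durations are therefore shorter than the
  full biomechanical phase durations, consistently across subjects.
- ICC(2,1) point estimates at 7–10 subjects carry wide CIs and a small
  negative bias; single-cohort estimates should be read with their
  intervals, not alone.
- `validate_trace` checks structural invariants, not physiological
  plausibility.
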