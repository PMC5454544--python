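# frtkin

Kinematic analysis of the **instrumented Functional Reach Test (FRT)**
from smartphone inertial logs.

The FRT is a clinical semistatic balance test: from a fixed standing
posture the subject reaches forward as far as possible and returns.
Clinically it is scored as a distance in cm on a wall tape, but a phone
strapped to the trunk (T7) and another to the lumbar spine (L5–S1)
record the movement's kinematics — how far the trunk pitches forward,
how long each phase takes, and at what speed.  `frtkin` turns those raw
sensor logs into the standard set of reach variables and quantifies how
reliably they can be measured, for researchers and clinicians working
on mobile balance assessment in populations with postural instability
(e.g. elderly post-stroke patients).

## What it computes

A reach is read off the pitch (forward-lean) angle as three events:
**A** (movement onset), **B** (maximum angular displacement) and **C**
(return to the initial posture).  B is the first sample attaining the
global maximum of the baseline-referenced pitch series; A and C are the
last/first samples at or below a threshold of 5% of the peak (C must
stay below it for 0.25 s).  For each interval I ∈ {A_B, B_C, A_C}:

- duration *t(I)* and angular displacement *θ(I)* (the **direct**
  variables), with A_C values exact sums of the two sub-intervals;
- mean speed *v(I) = θ(I)/t(I)* and mean acceleration
  *a(I) = v(I)/t(I)* (the **indirect** variables).

Per-axis summaries combine the three sensor axes by root-sum-of-squares
(resultant *r = √(x² + y² + z²)*).  Reliability uses the intraclass
correlation coefficient from the two-way random-effects ANOVA,
absolute-agreement, single-measures form — Shrout–Fleiss **ICC(2,1)** —
with 95% confidence bounds from the F distribution (consistency form
ICC(3,1) by flag), for both intraobserver (across repetitions) and
interobserver (across raters) designs, banded as very low (&lt; .30),
low, moderate, high, and very high (≥ .90).  Placement comparisons gate
a paired Student t vs Wilcoxon signed-rank on a Lilliefors
(Kolmogorov–Smirnov) normality test of the paired differences.

Because no public recordings of this protocol exist, the package ships
a first-class synthetic generator (`frtkin.simulate`): raised-cosine
reach trajectories sampled at 32 Hz with gravity-consistent
accelerometer, gyroscope and attitude channels, plus layered
subject/trial/observer variance components with known ground truth, so
every stage — segmentation, kinematics, reliability — is testable for
parameter recovery.

## Worked example

```python
from frtkin import (SimulationConfig, simulate_cohort, derive_pitch,
                    segment_reach, interval_kinematics, icc, round_half_away)

cohort = simulate_cohort(SimulationConfig(seed=1))   # 7 subjects x 3 reps x 2 phones

trace = cohort.traces[("S01", 1, "trunk")]
pitch, events = segment_reach(derive_pitch(trace), smooth_hz=0.3)
ik = interval_kinematics(pitch, events)
print(f"events: A={events.t_A:.2f}s  B={events.t_B:.2f}s  C={events.t_C:.2f}s  "
      f"peak={events.peak_deg:.2f} deg")
for name in ("A_B", "B_C", "A_C"):
    iv = ik.interval(name)
    print(f"{name}: time={round_half_away(iv.duration)} s  "
          f"displacement={round_half_away(iv.displacement)} deg  "
          f"speed={round_half_away(iv.speed)} deg/s  "
          f"acceleration={round_half_away(iv.acceleration)} deg/s^2")

res = icc(cohort.ratings("Displacement_A_B", "trunk", "intraobserver"))
print(f"intraobserver ICC(2,1) of Displacement_A_B (trunk): "
      f"{res.icc:.3f} (95% CI {res.ci_low:.3f}-{res.ci_high:.3f}), band: {res.band}")
```

prints

```
events: A=2.84s  B=12.16s  C=16.75s  peak=13.02 deg
A_B: time=9.31 s  displacement=12.38 deg  speed=1.33 deg/s  acceleration=0.14 deg/s^2
B_C: time=4.59 s  displacement=12.37 deg  speed=2.69 deg/s  acceleration=0.59 deg/s^2
A_C: time=13.91 s  displacement=24.75 deg  speed=1.78 deg/s  acceleration=0.13 deg/s^2
intraobserver ICC(2,1) of Displacement_A_B (trunk): 0.892 (95% CI 0.659-0.979), band: high
```

This subject took 9.31 s to pitch 12.38° forward (mean speed
1.33 °/s) and 4.59 s to return; one observer's three repetitions of the
rise displacement agree with an ICC of .892 — "high" reliability on the
conventional bands.

## Command line

The same workflow as a subcommand CLI:

```bash
frtkin simulate --seed 7 --out cohort/            # traces + ground truth + readings
frtkin extract --traces cohort/ --out kin.csv     # per-trial interval kinematics
frtkin compare --kinematics kin.csv --out cmp.csv # trunk vs lumbar, t/Wilcoxon-gated
frtkin reliability --readings cohort/readings.csv --out rel.csv --json rel.json
frtkin report --traces cohort/ --out report.json  # everything + provenance
```

Machine outputs keep full precision and declare a schema version;
human-facing tables round to 2 decimals (kinematics) and 3 decimals
(ICCs), half away from zero.

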