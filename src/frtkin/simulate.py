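"""Synthetic dual-placement reach trials and repeated-measures cohorts.

The generator emulates the study design the pipeline targets: a small
cohort of elderly post-stroke subjects, each performing three reach
repetitions wearing two phones (trunk and lumbar), read independently
by two observers.  Every stage has known ground truth, so segmentation,
kinematics and reliability estimation can all be tested for parameter
recovery without real recordings.

Model
-----
The pitch trajectory of one trial is a raised-cosine rise of duration
``rise_s`` to the trial amplitude, a brief plateau, and a raised-cosine
return of duration ``return_s`` — continuous velocity, bounded
acceleration, a smooth controlled reach.  The lumbar device shares the
trial's timing with the amplitude attenuated by ``lumbar_attenuation``
(the placements record one underlying movement).  Channels:

* attitude: true pitch (plus roll/yaw at 0) + white noise;
* accelerometer: gravity rotated through the pitch trajectory + white
  noise;
* gyroscope: the analytic pitch rate + white noise.

Variance components are layered subject -> trial -> observer reading:
subject-level amplitudes and phase durations come from lognormals
moment-matched to the configured mean/SD (amplitudes and durations are
positive and right-skewed; a matched normal would put mass below the
detection floor), trial effects are additive Gaussian, and an observer
reading perturbs the marked event instants/levels with Gaussian error.

All randomness flows from one root seed through named substreams
(subjects, trials, observers, sensor noise), so toggling one noise
source never reshuffles the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import InvalidConfig
from .reliability import RatingsMatrix
from .sensor_io import G_TO_MS2, SensorTrace


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and variance-component parameters of a cohort.

    Scale defaults follow the instrumented-reach setting the pipeline
    is built for: 7 subjects x 3 repetitions x 2 observers x 2
    placements at 32 Hz; trunk reach amplitude 12.6 +/- 5.2 deg between
    subjects, lumbar/trunk amplitude ratio 0.87; rise and return phases
    of 8.8 s and 7.2 s.
    """

    n_subjects: int = 7
    n_repetitions: int = 3
    n_observers: int = 2
    rate: float = 32.0

    amplitude_mean_deg: float = 12.6
    amplitude_sd_between_deg: float = 5.2
    lumbar_attenuation: float = 0.87
    rise_time_mean_s: float = 8.8
    return_time_mean_s: float = 7.2
    rise_time_sd_s: float = 1.3
    return_time_sd_s: float = 2.7

    within_subject_sd: float = 1.5        # trial-level amplitude SD, deg
    time_within_sd_s: float = 0.3         # trial-level phase-duration SD, s
    observer_sd: float = 0.5              # observer mark error on levels, deg
    observer_time_sd_s: float = 0.25      # observer mark error on instants, s

    sensor_noise_sd: float = 0.05         # accelerometer white noise, m/s^2
    attitude_noise_sd_deg: float = 0.5    # attitude channel white noise, deg
    gyro_noise_sd_dps: float = 0.5        # gyroscope white noise, deg/s

    frt_distance_mean_cm: float = 13.15
    frt_distance_sd_between_cm: float = 2.49
    frt_distance_within_sd_cm: float = 0.25
    frt_distance_observer_sd_cm: float = 0.1

    plateau_s: float = 0.3
    lead_in_s: float = 1.5
    tail_s: float = 2.0
    min_amplitude_deg: float = 4.0
    min_phase_s: float = 3.0
    truth_onset_fraction: float = 0.05

    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise InvalidConfig(f"n_subjects must be >= 2, got {self.n_subjects}")
        if self.n_repetitions < 1 or self.n_observers < 1:
            raise InvalidConfig("need >= 1 repetition and >= 1 observer")
        if self.rate <= 0:
            raise InvalidConfig(f"rate must be positive, got {self.rate}")
        for name in ("amplitude_sd_between_deg", "rise_time_sd_s", "return_time_sd_s",
                     "within_subject_sd", "time_within_sd_s", "observer_sd",
                     "observer_time_sd_s", "sensor_noise_sd", "attitude_noise_sd_deg",
                     "gyro_noise_sd_dps", "frt_distance_sd_between_cm",
                     "frt_distance_within_sd_cm", "frt_distance_observer_sd_cm",
                     "plateau_s", "tail_s"):
            if getattr(self, name) < 0:
                raise InvalidConfig(f"{name} must be >= 0")
        for name in ("amplitude_mean_deg", "rise_time_mean_s", "return_time_mean_s",
                     "lumbar_attenuation", "lead_in_s", "min_amplitude_deg",
                     "min_phase_s", "frt_distance_mean_cm"):
            if getattr(self, name) <= 0:
                raise InvalidConfig(f"{name} must be positive")
        if not (0.0 < self.truth_onset_fraction < 0.5):
            raise InvalidConfig("truth_onset_fraction must lie in (0, 0.5)")


@dataclass(frozen=True)
class TrialTruth:
    """Ground-truth bookkeeping for one simulated trial.

    ``t_A``/``t_B``/``t_C`` are the analytic event instants a
    threshold-based detector at ``onset_fraction`` should report: the
    onset-threshold crossing of the rise, the first instant at the
    peak, and the settling crossing of the return.  ``movement_start_s``
    and ``movement_end_s`` bracket the full motion.
    """

    subject_id: str
    repetition: int
    amplitude_trunk_deg: float
    amplitude_lumbar_deg: float
    rise_s: float
    plateau_s: float
    return_s: float
    lead_in_s: float
    onset_fraction: float
    t_A: float
    t_B: float
    t_C: float
    movement_start_s: float
    movement_end_s: float
    frt_distance_cm: Optional[float] = None

    def amplitude(self, placement: str) -> float:
        return self.amplitude_trunk_deg if placement == "trunk" else self.amplitude_lumbar_deg

    @property
    def peak_window(self) -> tuple[float, float]:
        """Interval over which the true trajectory attains its maximum.

        The maximum is held for the whole plateau, so the 'instant of
        maximum displacement' is set-valued; ``t_B`` is its first
        instant and this window is the full set.
        """
        return self.t_B, self.t_B + self.plateau_s

    def peak_time_error(self, detected_t_b: float) -> float:
        """Distance from a detected peak instant to the true peak set."""
        lo, hi = self.peak_window
        if detected_t_b < lo:
            return lo - detected_t_b
        if detected_t_b > hi:
            return detected_t_b - hi
        return 0.0


def _onset_factor(fraction: float) -> float:
    """Fraction of a raised-cosine phase elapsed at the onset threshold."""
    return math.acos(1.0 - 2.0 * fraction) / math.pi


def analytic_events(
    rise_s: float,
    plateau_s: float,
    return_s: float,
    lead_in_s: float,
    onset_fraction: float,
) -> tuple[float, float, float]:
    """Detector-consistent (t_A, t_B, t_C) of a raised-cosine trial."""
    c = _onset_factor(onset_fraction)
    t_a = lead_in_s + rise_s * c
    t_b = lead_in_s + rise_s
    t_c = lead_in_s + rise_s + plateau_s + return_s * (1.0 - c)
    return t_a, t_b, t_c


def _pitch_trajectory(t: np.ndarray, amplitude: float, rise_s: float,
                      plateau_s: float, return_s: float, lead_in_s: float) -> np.ndarray:
    y = np.zeros_like(t)
    r0, r1 = lead_in_s, lead_in_s + rise_s
    p1 = r1 + plateau_s
    q1 = p1 + return_s
    m = (t >= r0) & (t < r1)
    y[m] = amplitude / 2.0 * (1.0 - np.cos(np.pi * (t[m] - r0) / rise_s))
    y[(t >= r1) & (t < p1)] = amplitude
    m = (t >= p1) & (t < q1)
    y[m] = amplitude / 2.0 * (1.0 + np.cos(np.pi * (t[m] - p1) / return_s))
    return y


def _pitch_rate(t: np.ndarray, amplitude: float, rise_s: float,
                plateau_s: float, return_s: float, lead_in_s: float) -> np.ndarray:
    w = np.zeros_like(t)
    r0, r1 = lead_in_s, lead_in_s + rise_s
    p1 = r1 + plateau_s
    q1 = p1 + return_s
    m = (t >= r0) & (t < r1)
    w[m] = amplitude * np.pi / (2.0 * rise_s) * np.sin(np.pi * (t[m] - r0) / rise_s)
    m = (t >= p1) & (t < q1)
    w[m] = -amplitude * np.pi / (2.0 * return_s) * np.sin(np.pi * (t[m] - p1) / return_s)
    return w


def _placement_trace(
    t: np.ndarray,
    amplitude: float,
    rise_s: float,
    plateau_s: float,
    return_s: float,
    config: SimulationConfig,
    placement: str,
    rng: np.random.Generator,
) -> SensorTrace:
    pitch = _pitch_trajectory(t, amplitude, rise_s, plateau_s, return_s, config.lead_in_s)
    rate_dps = _pitch_rate(t, amplitude, rise_s, plateau_s, return_s, config.lead_in_s)
    theta = np.radians(pitch)
    n = t.shape[0]
    acc = np.column_stack([
        np.zeros(n),                 # lateral
        G_TO_MS2 * np.cos(theta),    # vertical (long axis)
        G_TO_MS2 * np.sin(theta),    # forward
    ]) + rng.normal(0.0, config.sensor_noise_sd, (n, 3))
    gyro = np.column_stack([rate_dps, np.zeros(n), np.zeros(n)])
    gyro = gyro + rng.normal(0.0, config.gyro_noise_sd_dps, (n, 3))
    attitude = np.column_stack([pitch, np.zeros(n), np.zeros(n)])
    attitude = attitude + rng.normal(0.0, config.attitude_noise_sd_deg, (n, 3))
    return SensorTrace(
        t=t.copy(),
        acc=acc,
        gyro=gyro,
        attitude=attitude,
        placement=placement,
        nominal_rate=config.rate,
        device_label=f"synthetic-{placement}",
    )


def simulate_trial(
    config: SimulationConfig,
    *,
    amplitude_deg: Optional[float] = None,
    rise_s: Optional[float] = None,
    return_s: Optional[float] = None,
    frt_distance_cm: Optional[float] = None,
    subject_id: str = "S1",
    repetition: int = 1,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[SensorTrace, SensorTrace, TrialTruth]:
    """Simulate one trial's trunk and lumbar traces with ground truth.

    Trial parameters default to the configured means; the only
    randomness inside a trial is sensor noise, drawn from ``seed``
    (same seed, same parameters -> identical traces).
    """
    config.validate()
    amplitude = config.amplitude_mean_deg if amplitude_deg is None else float(amplitude_deg)
    rise = config.rise_time_mean_s if rise_s is None else float(rise_s)
    ret = config.return_time_mean_s if return_s is None else float(return_s)
    if amplitude <= 0 or rise <= 0 or ret <= 0:
        raise InvalidConfig("trial amplitude and phase durations must be positive")

    duration = config.lead_in_s + rise + config.plateau_s + ret + config.tail_s
    n = int(round(duration * config.rate))
    t = np.arange(n) / config.rate
    rng = np.random.default_rng(seed)
    rng_trunk, rng_lumbar = rng.spawn(2)

    trunk = _placement_trace(t, amplitude, rise, config.plateau_s, ret,
                             config, "trunk", rng_trunk)
    amp_lumbar = amplitude * config.lumbar_attenuation
    lumbar = _placement_trace(t, amp_lumbar, rise, config.plateau_s, ret,
                              config, "lumbar", rng_lumbar)
    t_a, t_b, t_c = analytic_events(rise, config.plateau_s, ret,
                                    config.lead_in_s, config.truth_onset_fraction)
    truth = TrialTruth(
        subject_id=subject_id,
        repetition=repetition,
        amplitude_trunk_deg=amplitude,
        amplitude_lumbar_deg=amp_lumbar,
        rise_s=rise,
        plateau_s=config.plateau_s,
        return_s=ret,
        lead_in_s=config.lead_in_s,
        onset_fraction=config.truth_onset_fraction,
        t_A=t_a,
        t_B=t_b,
        t_C=t_c,
        movement_start_s=config.lead_in_s,
        movement_end_s=config.lead_in_s + rise + config.plateau_s + ret,
        frt_distance_cm=frt_distance_cm,
    )
    return trunk, lumbar, truth


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Lognormal draws moment-matched to (mean, sd); constant when sd=0."""
    if sd == 0.0:
        return np.full(size, mean)
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size)


#: Variables for which observer readings are generated, per placement.
READING_VARIABLES = (
    "Time_A_B", "Time_B_C", "Time_A_C",
    "Displacement_A_B", "Displacement_B_C", "Displacement_A_C",
)


@dataclass
class Cohort:
    """A simulated repeated-measures dataset with its ground truth."""

    config: SimulationConfig
    traces: dict[tuple[str, int, str], SensorTrace]
    truths: list[TrialTruth]
    readings: pd.DataFrame  # subject, repetition, observer, placement, variable, value

    def truth_for(self, subject_id: str, repetition: int) -> TrialTruth:
        for tr in self.truths:
            if (tr.subject_id, tr.repetition) == (subject_id, repetition):
                return tr
        raise KeyError((subject_id, repetition))

    def ratings(
        self,
        variable: str,
        placement: str = "trunk",
        mode: str = "intraobserver",
        observer: int = 1,
        repetition: int = 1,
    ) -> RatingsMatrix:
        """Subjects x columns grid of one variable's observer readings.

        Intraobserver: one observer's readings across repetitions.
        Interobserver: all observers' readings of one repetition.
        """
        df = self.readings
        sel = (df["variable"] == variable) & (df["placement"] == placement)
        if mode == "intraobserver":
            sub = df[sel & (df["observer"] == observer)]
            grid = sub.pivot(index="subject", columns="repetition", values="value")
        elif mode == "interobserver":
            sub = df[sel & (df["repetition"] == repetition)]
            grid = sub.pivot(index="subject", columns="observer", values="value")
        else:
            raise ValueError(f"unknown mode {mode!r}")
        return RatingsMatrix(values=grid.to_numpy(float), mode=mode)

    def true_icc(self, variable: str, placement: str = "trunk",
                 mode: str = "intraobserver") -> float:
        return true_icc(self.config, variable, placement=placement, mode=mode)


def simulate_cohort(config: SimulationConfig | None = None) -> Cohort:
    """Simulate the full repeated-measures design of one cohort."""
    config = config or SimulationConfig()
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    ss_subj, ss_trial, ss_obs, ss_sensor = ss.spawn(4)
    rng_subj = np.random.default_rng(ss_subj)
    rng_trial = np.random.default_rng(ss_trial)
    rng_obs = np.random.default_rng(ss_obs)
    sensor_children = ss_sensor.spawn(config.n_subjects * config.n_repetitions)

    n_s, n_r = config.n_subjects, config.n_repetitions
    amp_subj = _lognormal(rng_subj, config.amplitude_mean_deg,
                          config.amplitude_sd_between_deg, n_s)
    rise_subj = _lognormal(rng_subj, config.rise_time_mean_s,
                           config.rise_time_sd_s, n_s)
    ret_subj = _lognormal(rng_subj, config.return_time_mean_s,
                          config.return_time_sd_s, n_s)
    frt_subj = _lognormal(rng_subj, config.frt_distance_mean_cm,
                          config.frt_distance_sd_between_cm, n_s)

    traces: dict[tuple[str, int, str], SensorTrace] = {}
    truths: list[TrialTruth] = []
    rows: list[dict] = []
    trial_idx = 0
    for i in range(n_s):
        sid = f"S{i + 1:02d}"
        for rep in range(1, n_r + 1):
            amp = max(config.min_amplitude_deg,
                      amp_subj[i] + rng_trial.normal(0.0, config.within_subject_sd))
            rise = max(config.min_phase_s,
                       rise_subj[i] + rng_trial.normal(0.0, config.time_within_sd_s))
            ret = max(config.min_phase_s,
                      ret_subj[i] + rng_trial.normal(0.0, config.time_within_sd_s))
            frt = max(0.1, frt_subj[i]
                      + rng_trial.normal(0.0, config.frt_distance_within_sd_cm))
            trunk, lumbar, truth = simulate_trial(
                config,
                amplitude_deg=amp,
                rise_s=rise,
                return_s=ret,
                frt_distance_cm=frt,
                subject_id=sid,
                repetition=rep,
                seed=sensor_children[trial_idx],
            )
            trial_idx += 1
            traces[(sid, rep, "trunk")] = trunk
            traces[(sid, rep, "lumbar")] = lumbar
            truths.append(truth)
            rows.extend(_observer_readings(config, truth, rng_obs))
    readings = pd.DataFrame(rows)
    return Cohort(config=config, traces=traces, truths=truths, readings=readings)


def _observer_readings(
    config: SimulationConfig, truth: TrialTruth, rng: np.random.Generator
) -> list[dict]:
    """Each observer marks the event instants and levels with error.

    An observer reading perturbs the three instants (SD
    ``observer_time_sd_s``) and the three levels — start, peak, end —
    (SD ``observer_sd``), then derives durations and displacements from
    the marks, so a single observer's readings are internally additive.
    """
    rows = []
    for obs in range(1, config.n_observers + 1):
        for placement in ("trunk", "lumbar"):
            amp = truth.amplitude(placement)
            ta, tb, tc = (truth.t_A + rng.normal(0.0, config.observer_time_sd_s),
                          truth.t_B + rng.normal(0.0, config.observer_time_sd_s),
                          truth.t_C + rng.normal(0.0, config.observer_time_sd_s))
            start, peak, end = (rng.normal(0.0, config.observer_sd),
                                amp + rng.normal(0.0, config.observer_sd),
                                rng.normal(0.0, config.observer_sd))
            values = {
                "Time_A_B": tb - ta,
                "Time_B_C": tc - tb,
                "Time_A_C": tc - ta,
                "Displacement_A_B": peak - start,
                "Displacement_B_C": peak - end,
                "Displacement_A_C": 2.0 * peak - start - end,
            }
            rows.extend(
                {"subject": truth.subject_id, "repetition": truth.repetition,
                 "observer": obs, "placement": placement, "variable": var,
                 "value": val}
                for var, val in values.items()
            )
        rows.append(
            {"subject": truth.subject_id, "repetition": truth.repetition,
             "observer": obs, "placement": "tape", "variable": "FRT_distance_cm",
             "value": truth.frt_distance_cm
             + rng.normal(0.0, config.frt_distance_observer_sd_cm)}
        )
    return rows


def _variance_components(
    config: SimulationConfig, variable: str, placement: str
) -> tuple[float, float, float]:
    """(subject, trial, observer-reading) variances of one variable."""
    c = _onset_factor(config.truth_onset_fraction)
    scale = 1.0 - c  # measured duration fraction of a raised-cosine phase
    att = 1.0 if placement == "trunk" else config.lumbar_attenuation
    ot2 = config.observer_time_sd_s ** 2
    ol2 = config.observer_sd ** 2
    tw2 = config.time_within_sd_s ** 2
    if variable == "Time_A_B":
        return (scale * config.rise_time_sd_s) ** 2, scale ** 2 * tw2, 2 * ot2
    if variable == "Time_B_C":
        return (scale * config.return_time_sd_s) ** 2, scale ** 2 * tw2, 2 * ot2
    if variable == "Time_A_C":
        subj = scale ** 2 * (config.rise_time_sd_s ** 2 + config.return_time_sd_s ** 2)
        return subj, scale ** 2 * 2 * tw2, 2 * ot2
    if variable in ("Displacement_A_B", "Displacement_B_C"):
        return ((att * config.amplitude_sd_between_deg) ** 2,
                (att * config.within_subject_sd) ** 2, 2 * ol2)
    if variable == "Displacement_A_C":
        return ((2 * att * config.amplitude_sd_between_deg) ** 2,
                (2 * att * config.within_subject_sd) ** 2, 6 * ol2)
    if variable == "FRT_distance_cm":
        return (config.frt_distance_sd_between_cm ** 2,
                config.frt_distance_within_sd_cm ** 2,
                config.frt_distance_observer_sd_cm ** 2)
    raise InvalidConfig(f"unknown variable {variable!r}")


def true_icc(
    config: SimulationConfig,
    variable: str,
    placement: str = "trunk",
    mode: str = "intraobserver",
) -> float:
    """The ICC implied by the generating variance components.

    Intraobserver (one observer, columns = repetitions): between =
    subject variance, within = trial + reading variance.  Interobserver
    (columns = observers reading the same trial): the trial effect is
    shared, so it joins the between-subject part.
    """
    config.validate()
    s2_subj, s2_trial, s2_obs = _variance_components(config, variable, placement)
    if mode == "intraobserver":
        between, within = s2_subj, s2_trial + s2_obs
    elif mode == "interobserver":
        between, within = s2_subj + s2_trial, s2_obs
    else:
        raise ValueError(f"unknown mode {mode!r}")
    total = between + within
    return 1.0 if total == 0.0 else between / total


def simulate_ratings(
    n_subjects: int,
    n_columns: int,
    target_icc: float,
    rng: np.random.Generator | int | None = None,
    mode: str = "intraobserver",
) -> RatingsMatrix:
    """Ratings grid with a programmed true ICC.

    Subject effects N(0, rho) plus reading noise N(0, 1-rho), so the
    implied intraclass correlation is exactly ``target_icc``.
    """
    if not (0.0 <= target_icc <= 1.0):
        raise InvalidConfig(f"target_icc must lie in [0, 1], got {target_icc}")
    rng = np.random.default_rng(rng)
    subj = rng.normal(0.0, math.sqrt(target_icc), (n_subjects, 1))
    noise = rng.normal(0.0, math.sqrt(1.0 - target_icc), (n_subjects, n_columns))
    return RatingsMatrix(values=subj + noise, mode=mode)


def trace_filename(subject_id: str, repetition: int, placement: str) -> str:
    return f"{subject_id}_rep{repetition}_{placement}.csv"


def write_cohort(cohort: Cohort, outdir: Union[str, Path]) -> None:
    """Write a cohort as default-dialect trace CSVs plus a ground-truth
    manifest (truth.csv) and the observer readings (readings.csv)."""
    from .sensor_io import write_sensor_log

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (sid, rep, placement), trace in cohort.traces.items():
        write_sensor_log(trace, outdir / trace_filename(sid, rep, placement))
    pd.DataFrame([asdict(tr) for tr in cohort.truths]).to_csv(
        outdir / "truth.csv", index=False
    )
    cohort.readings.to_csv(outdir / "readings.csv", index=False)
    import json

    (outdir / "config.json").write_text(
        json.dumps(config_to_mapping(cohort.config), indent=2, sort_keys=True) + "\n"
    )


def config_from_mapping(data: dict) -> SimulationConfig:
    """Build a config from a YAML/JSON mapping, rejecting unknown keys."""
    known = {f.name for f in SimulationConfig.__dataclass_fields__.values()}
    unknown = set(data) - known
    if unknown:
        raise InvalidConfig(f"unknown simulation config keys: {sorted(unknown)}")
    cfg = SimulationConfig(**data)
    cfg.validate()
    return cfg


def config_to_mapping(config: SimulationConfig) -> dict:
    return asdict(config)
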