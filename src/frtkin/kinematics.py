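"""Direct and indirect kinematic variables of one reach.

Direct variables are the phase durations and angular displacements read
from the pitch record between the A/B/C events.  Indirect variables are
ratios of those: the mean speed of an interval is displacement/duration
and its mean acceleration is speed/duration (equivalently
displacement/duration^2) — the ratio convention, applied per interval,
that the printed reference tables follow.  Totals over A_C are sums of
the two sub-intervals, exactly.

The per-axis summary treats each sensor axis separately over [t_A, t_C]
(max/min/mean of angular velocity and of acceleration) and combines the
three axes' corresponding statistics by root-sum-of-squares into the
resultants.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import InconsistentEvents, MismatchedTrials, MissingChannels
from .preprocess import PitchSeries
from .segmentation import PhaseEvents

INTERVALS = ("A_B", "B_C", "A_C")

#: Column order of the per-trial kinematics table, matching the printed
#: reference layout.
KINEMATIC_COLUMNS = tuple(
    f"{q}_{iv}" for iv in INTERVALS for q in ("Time", "Displacement", "Speed", "Acceleration")
)


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of the printed tables;
    banker's rounding would turn 0.155 into 0.15, not 0.16)."""
    d = decimal.Decimal(repr(float(x))).quantize(
        decimal.Decimal(1).scaleb(-ndigits), rounding=decimal.ROUND_HALF_UP
    )
    return float(d)


def resultant(x: float, y: float, z: float) -> float:
    """Root-sum-of-squares of the three axis components."""
    x, y, z = float(x), float(y), float(z)
    return float(np.sqrt(x * x + y * y + z * z))


@dataclass(frozen=True)
class Interval:
    """Kinematics of one movement interval."""

    duration: float       # s
    displacement: float   # deg
    speed: float          # deg/s
    acceleration: float   # deg/s^2


@dataclass(frozen=True)
class IntervalKinematics:
    """The A_B (rise), B_C (return) and A_C (total) interval variables.

    Invariants: A_C duration and displacement are exact sums of the two
    sub-intervals; each interval's speed*duration equals its displacement
    and acceleration*duration equals its speed.
    """

    a_b: Interval
    b_c: Interval
    a_c: Interval

    def interval(self, name: str) -> Interval:
        return {"A_B": self.a_b, "B_C": self.b_c, "A_C": self.a_c}[name]

    def to_row(self) -> dict[str, float]:
        row: dict[str, float] = {}
        for name in INTERVALS:
            iv = self.interval(name)
            row[f"Time_{name}"] = iv.duration
            row[f"Displacement_{name}"] = iv.displacement
            row[f"Speed_{name}"] = iv.speed
            row[f"Acceleration_{name}"] = iv.acceleration
        return row


def _make_interval(duration: float, displacement: float) -> Interval:
    speed = displacement / duration
    return Interval(
        duration=duration,
        displacement=displacement,
        speed=speed,
        acceleration=speed / duration,
    )


def make_interval_kinematics(
    dur_ab: float, disp_ab: float, dur_bc: float, disp_bc: float
) -> IntervalKinematics:
    """Build the three intervals from the rise/return durations and
    displacements; the total is their exact sum."""
    if dur_ab <= 0 or dur_bc <= 0:
        raise InconsistentEvents("interval durations must be positive")
    if disp_ab < 0 or disp_bc < 0:
        raise InconsistentEvents("interval displacements must be non-negative")
    return IntervalKinematics(
        a_b=_make_interval(dur_ab, disp_ab),
        b_c=_make_interval(dur_bc, disp_bc),
        a_c=_make_interval(dur_ab + dur_bc, disp_ab + disp_bc),
    )


def interval_kinematics(pitch: PitchSeries, events: PhaseEvents) -> IntervalKinematics:
    """Interval variables of one reach from its pitch series and events."""
    for idx, t in ((events.i_A, events.t_A), (events.i_B, events.t_B),
                   (events.i_C, events.t_C)):
        if not (0 <= idx < pitch.n):
            raise InconsistentEvents(f"event index {idx} outside series of {pitch.n}")
        if abs(pitch.time_at(idx) - t) > 1e-9:
            raise InconsistentEvents(
                f"event time {t} does not lie on the series grid (index {idx})"
            )
    if not (events.i_A < events.i_B < events.i_C):
        raise InconsistentEvents("events must be ordered A < B < C")
    v = pitch.values
    return make_interval_kinematics(
        dur_ab=events.t_B - events.t_A,
        disp_ab=abs(float(v[events.i_B] - v[events.i_A])),
        dur_bc=events.t_C - events.t_B,
        disp_bc=abs(float(v[events.i_B] - v[events.i_C])),
    )


@dataclass(frozen=True)
class AxisStats:
    max: float
    min: float
    mean: float


@dataclass(frozen=True)
class QuantitySummary:
    """Per-axis max/min/mean of one quantity plus the RSS resultants."""

    x: AxisStats
    y: AxisStats
    z: AxisStats
    resultant: AxisStats

    @classmethod
    def from_samples(cls, samples: np.ndarray) -> "QuantitySummary":
        per_axis = [
            AxisStats(
                max=float(samples[:, j].max()),
                min=float(samples[:, j].min()),
                mean=float(samples[:, j].mean()),
            )
            for j in range(3)
        ]
        res = AxisStats(
            max=resultant(*(a.max for a in per_axis)),
            min=resultant(*(a.min for a in per_axis)),
            mean=resultant(*(a.mean for a in per_axis)),
        )
        return cls(x=per_axis[0], y=per_axis[1], z=per_axis[2], resultant=res)


@dataclass(frozen=True)
class AxisSummary:
    """Per-axis and resultant statistics over [t_A, t_C]."""

    speed: QuantitySummary          # angular velocity, deg/s
    acceleration: QuantitySummary   # linear acceleration, m/s^2
    resultant_displacement: float   # deg
    velocity_source: str            # 'gyroscope' or 'attitude_derivative'

    def to_row(self) -> dict[str, float]:
        row: dict[str, float] = {"Resultant displacement": self.resultant_displacement}
        for qname, q in (("Speed", self.speed), ("Acceleration", self.acceleration)):
            for stat in ("mean", "max", "min"):
                for ax in ("x", "y", "z"):
                    row[f"{qname} {stat} {ax.upper()}"] = getattr(getattr(q, ax), stat)
                row[f"Resultant {qname.lower()} {stat}"] = getattr(q.resultant, stat)
        return row


def axis_summary(trace, events: PhaseEvents) -> AxisSummary:
    """Per-axis velocity/acceleration statistics of the reach window.

    Angular velocity comes from the gyroscope when recorded, otherwise
    from the finite-difference derivative of the attitude angles.
    Acceleration comes from the accelerometer.  Per-axis displacement
    (for the resultant displacement) is the attitude range per axis, or
    the range of the integrated gyroscope when attitude is absent.
    """
    window = (trace.t >= events.t_A - 1e-9) & (trace.t <= events.t_C + 1e-9)
    if not window.any():
        raise InconsistentEvents("events lie outside the trace time span")
    dt = 1.0 / trace.nominal_rate

    if trace.gyro is not None:
        omega = trace.gyro
        vel_source = "gyroscope"
    elif trace.attitude is not None:
        omega = np.gradient(trace.attitude, dt, axis=0)
        vel_source = "attitude_derivative"
    else:
        raise MissingChannels("neither gyroscope nor attitude channels present")
    if trace.acc is None:
        raise MissingChannels("accelerometer channels required for the summary")

    if trace.attitude is not None:
        orient = trace.attitude[window]
    else:  # orientation change from the gyroscope
        from scipy.integrate import cumulative_trapezoid

        orient = cumulative_trapezoid(trace.gyro[window], dx=dt, axis=0, initial=0.0)
    disp = orient.max(axis=0) - orient.min(axis=0)

    return AxisSummary(
        speed=QuantitySummary.from_samples(omega[window]),
        acceleration=QuantitySummary.from_samples(trace.acc[window]),
        resultant_displacement=resultant(*disp),
        velocity_source=vel_source,
    )


@dataclass
class TrialResult:
    """Everything extracted from one (subject, trial, placement) recording."""

    subject_id: str
    placement: str
    repetition: int
    events: PhaseEvents
    intervals: IntervalKinematics
    axes: Optional[AxisSummary] = None
    frt_distance_cm: Optional[float] = None

    def to_row(self) -> dict:
        row: dict = {
            "subject_id": self.subject_id,
            "placement": self.placement,
            "repetition": self.repetition,
        }
        if self.frt_distance_cm is not None:
            row["FRT_distance_cm"] = self.frt_distance_cm
        row.update(self.intervals.to_row())
        row["Peak_displacement_deg"] = self.events.peak_deg
        return row


def results_table(results: Iterable[TrialResult]) -> pd.DataFrame:
    """One row per (subject, repetition, placement), reference layout."""
    return pd.DataFrame([r.to_row() for r in results])


def placement_difference(trunk: TrialResult, lumbar: TrialResult) -> pd.DataFrame:
    """Per-variable trunk - lumbar differences for one trial."""
    if trunk.placement == lumbar.placement:
        raise MismatchedTrials("need one trunk and one lumbar result")
    if (trunk.subject_id, trunk.repetition) != (lumbar.subject_id, lumbar.repetition):
        raise MismatchedTrials(
            f"trunk {(trunk.subject_id, trunk.repetition)} vs "
            f"lumbar {(lumbar.subject_id, lumbar.repetition)}"
        )
    t_row, l_row = trunk.intervals.to_row(), lumbar.intervals.to_row()
    if trunk.axes is not None and lumbar.axes is not None:
        t_row.update(trunk.axes.to_row())
        l_row.update(lumbar.axes.to_row())
    rows = [
        {"variable": k, "trunk": t_row[k], "lumbar": l_row[k],
         "difference": t_row[k] - l_row[k]}
        for k in t_row
    ]
    return pd.DataFrame(rows)


def cohort_differences(pairs: Iterable[tuple[TrialResult, TrialResult]]) -> pd.DataFrame:
    """Mean and SD of the per-trial trunk - lumbar differences.

    Each element of ``pairs`` is one trial's (trunk, lumbar) results;
    the aggregate is the mean of per-trial differences, not the
    difference of aggregate means.
    """
    frames = [placement_difference(t, l).assign(trial=i) for i, (t, l) in enumerate(pairs)]
    if not frames:
        raise MismatchedTrials("no trials to aggregate")
    df = pd.concat(frames, ignore_index=True)
    agg = df.groupby("variable", sort=False).agg(
        trunk_mean=("trunk", "mean"),
        trunk_sd=("trunk", lambda s: s.std(ddof=1)),
        lumbar_mean=("lumbar", "mean"),
        lumbar_sd=("lumbar", lambda s: s.std(ddof=1)),
        difference_mean=("difference", "mean"),
        difference_sd=("difference", lambda s: s.std(ddof=1)),
        n=("difference", "size"),
    )
    return agg.reset_index()


def format_kinematics(df: pd.DataFrame, ndigits: int = 2) -> pd.DataFrame:
    """Human-facing copy of a table, rounded half-away-from-zero."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda x: round_half_away(x, ndigits))
    return out
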