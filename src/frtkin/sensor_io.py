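"""Reading, validating and writing smartphone sensor logs.

A *trace* is one placement's recording of one trial: a strictly
increasing time base plus tri-axial accelerometer (m/s^2) and, when the
recording app provides them, gyroscope (deg/s) and attitude
(pitch/roll/yaw, deg) channels.  Logs are plain CSV; the column naming
and units of a given recorder app are described by a :class:`LogDialect`
so the reader is not tied to one vendor schema.

Internally everything is SI-ish: seconds from the first sample, m/s^2,
degrees.  Logs that store acceleration in g are converted at read time
(1 g = 9.80665 m/s^2).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Optional, Union

import numpy as np
import pandas as pd

from .errors import EmptyLog, MalformedLog

G_TO_MS2 = 9.80665

#: Raw timestamps larger than this are taken to be absolute epoch times
#: rather than seconds from the start of the recording.
_EPOCH_THRESHOLD = 1e6

PLACEMENTS = ("trunk", "lumbar")


@dataclass(frozen=True)
class LogDialect:
    """Column mapping and unit conventions of one recorder app's CSV."""

    name: str
    time_col: str = "time"
    acc_cols: Optional[tuple[str, str, str]] = ("acc_x", "acc_y", "acc_z")
    gyro_cols: Optional[tuple[str, str, str]] = ("gyro_x", "gyro_y", "gyro_z")
    attitude_cols: Optional[tuple[str, str, str]] = ("pitch", "roll", "yaw")
    acc_in_g: bool = False
    decimal: str = "."
    sep: str = ","


#: Default dialect: header row, comma separator, relative-or-epoch
#: timestamps autodetected, accelerations already in m/s^2.
SENSORLOG = LogDialect(name="sensorlog")

DIALECTS: dict[str, LogDialect] = {"sensorlog": SENSORLOG}


def register_dialect(dialect: LogDialect) -> None:
    DIALECTS[dialect.name] = dialect


def _as_dialect(dialect: Union[str, LogDialect, None]) -> LogDialect:
    if dialect is None:
        return SENSORLOG
    if isinstance(dialect, LogDialect):
        return dialect
    try:
        return DIALECTS[dialect]
    except KeyError:
        raise MalformedLog(f"unknown log dialect {dialect!r}") from None


@dataclass
class SensorTrace:
    """One placement's raw multi-channel recording of one trial.

    Channel arrays are ``(n, 3)`` float arrays aligned with ``t``; absent
    channels are ``None``.  ``t`` is seconds from the first sample;
    ``t_start`` keeps the original absolute timestamp of that sample when
    the log carried one.
    """

    t: np.ndarray
    acc: Optional[np.ndarray] = None
    gyro: Optional[np.ndarray] = None
    attitude: Optional[np.ndarray] = None
    placement: str = "trunk"
    nominal_rate: float = 32.0
    device_label: str = ""
    t_start: Optional[float] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("acc", "gyro", "attitude"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))

    @property
    def n_samples(self) -> int:
        return int(self.t.shape[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.n_samples else 0.0

    def channels(self) -> dict[str, np.ndarray]:
        """Present channel blocks, keyed 'acc'/'gyro'/'attitude'."""
        out = {}
        for name in ("acc", "gyro", "attitude"):
            v = getattr(self, name)
            if v is not None:
                out[name] = v
        return out

    def replace(self, **kw) -> "SensorTrace":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class SubjectRecord:
    """Per-subject metadata: clinical scores and the tape-measured reach.

    Scores are carried as inputs only; the pipeline never derives the
    reach distance in cm from the angular record.
    """

    subject_id: str
    age: Optional[float] = None
    barthel: Optional[float] = None
    sis16: Optional[float] = None
    cns: Optional[float] = None
    frt_distance_cm: Optional[float] = None

    _RANGES = {
        "age": (0.0, 130.0),
        "barthel": (0.0, 100.0),
        "sis16": (0.0, 100.0),
        "cns": (0.0, 11.5),
        "frt_distance_cm": (0.0, 100.0),
    }

    def validate(self) -> list[str]:
        """Names of fields outside their instrument's range."""
        bad = []
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if v is not None and not (lo <= v <= hi):
                bad.append(name)
        return bad


@dataclass(frozen=True)
class Issue:
    """One violated trace invariant, with the first offending index."""

    invariant: str
    index: Optional[int]
    message: str


def read_sensor_log(
    source: Union[str, Path, IO[str]],
    dialect: Union[str, LogDialect, None] = None,
    *,
    placement: str = "trunk",
    nominal_rate: float = 32.0,
    device_label: str = "",
) -> SensorTrace:
    """Parse a CSV sensor log into a :class:`SensorTrace`.

    Unknown columns are ignored; times are converted to seconds from the
    first sample (epoch timestamps autodetected).  Raises
    :class:`MalformedLog` on unparseable rows or missing mandatory
    columns and :class:`EmptyLog` on a file with zero samples.
    """
    d = _as_dialect(dialect)
    try:
        df = pd.read_csv(source, sep=d.sep, decimal=d.decimal)
    except pd.errors.EmptyDataError:
        raise EmptyLog(f"{source}: no samples") from None
    except Exception as exc:  # parser errors, IO errors on bad content
        raise MalformedLog(f"{source}: {exc}") from exc
    if df.shape[0] == 0:
        raise EmptyLog(f"{source}: no samples")

    if d.time_col not in df.columns:
        raise MalformedLog(f"{source}: missing time column {d.time_col!r}")

    def _block(cols: Optional[tuple[str, str, str]]) -> Optional[np.ndarray]:
        if cols is None or not all(c in df.columns for c in cols):
            return None
        try:
            return np.column_stack(
                [pd.to_numeric(df[c], errors="raise").to_numpy(float) for c in cols]
            )
        except (ValueError, TypeError) as exc:
            raise MalformedLog(f"{source}: non-numeric values in {cols}: {exc}") from exc

    try:
        t_raw = pd.to_numeric(df[d.time_col], errors="raise").to_numpy(float)
    except (ValueError, TypeError) as exc:
        raise MalformedLog(f"{source}: non-numeric timestamps: {exc}") from exc

    acc = _block(d.acc_cols)
    gyro = _block(d.gyro_cols)
    attitude = _block(d.attitude_cols)
    if acc is None and attitude is None:
        raise MalformedLog(
            f"{source}: neither acceleration columns {d.acc_cols} nor "
            f"attitude columns {d.attitude_cols} present"
        )
    if acc is not None and d.acc_in_g:
        acc = acc * G_TO_MS2

    t_start = float(t_raw[0]) if (math.isfinite(t_raw[0]) and abs(t_raw[0]) > _EPOCH_THRESHOLD) else None
    t = t_raw - t_raw[0]
    return SensorTrace(
        t=t,
        acc=acc,
        gyro=gyro,
        attitude=attitude,
        placement=placement,
        nominal_rate=nominal_rate,
        device_label=device_label,
        t_start=t_start,
    )


def write_sensor_log(
    trace: SensorTrace,
    dest: Union[str, Path, IO[str]],
    *,
    float_format: str = "%.10g",
) -> None:
    """Write a trace as a default-dialect CSV re-readable by
    :func:`read_sensor_log`.  Refuses zero-sample traces."""
    if trace.n_samples == 0:
        raise EmptyLog("refusing to write a zero-sample trace")
    cols: dict[str, np.ndarray] = {"time": trace.t}
    for name, block_cols in (
        ("acc", SENSORLOG.acc_cols),
        ("gyro", SENSORLOG.gyro_cols),
        ("attitude", SENSORLOG.attitude_cols),
    ):
        block = getattr(trace, name)
        if block is not None:
            for j, c in enumerate(block_cols):
                cols[c] = block[:, j]
    pd.DataFrame(cols).to_csv(dest, index=False, float_format=float_format)


def validate_trace(trace: SensorTrace) -> list[Issue]:
    """Check every trace invariant; empty list iff the trace is valid.

    Total: never raises, whatever ended up inside the trace.
    """
    issues: list[Issue] = []
    try:
        t = np.asarray(trace.t, dtype=float)
    except Exception:
        return [Issue("time_numeric", None, "time base is not numeric")]

    n = t.shape[0] if t.ndim == 1 else -1
    if t.ndim != 1 or n == 0:
        issues.append(Issue("nonempty", None, "trace has no samples"))
        return issues

    bad = np.nonzero(~np.isfinite(t))[0]
    if bad.size:
        issues.append(Issue("time_finite", int(bad[0]),
                            f"non-finite timestamp at index {bad[0]}"))
    elif t[0] < 0:
        issues.append(Issue("time_nonnegative", 0, "first timestamp is negative"))
    else:
        nonmono = np.nonzero(np.diff(t) <= 0)[0]
        if nonmono.size:
            i = int(nonmono[0]) + 1
            issues.append(Issue("time_strictly_increasing", i,
                                f"timestamp at index {i} does not increase"))

    present = 0
    for name in ("acc", "gyro", "attitude"):
        block = getattr(trace, name)
        if block is None:
            continue
        block = np.asarray(block)
        if block.shape != (n, 3):
            issues.append(Issue(f"{name}_shape", None,
                                f"{name} has shape {block.shape}, expected {(n, 3)}"))
            continue
        if name in ("acc", "attitude"):
            present += 1
        bad = np.nonzero(~np.isfinite(block).all(axis=1))[0]
        if bad.size:
            issues.append(Issue(f"{name}_finite", int(bad[0]),
                                f"non-finite {name} value at index {bad[0]}"))
    if present == 0:
        issues.append(Issue("channels_present", None,
                            "neither acceleration nor attitude channels present"))

    rate = trace.nominal_rate
    if not (isinstance(rate, (int, float)) and math.isfinite(rate) and rate > 0):
        issues.append(Issue("rate_positive", None,
                            f"nominal_rate {rate!r} is not a positive number"))
    if trace.placement not in PLACEMENTS:
        issues.append(Issue("placement_known", None,
                            f"placement {trace.placement!r} not in {PLACEMENTS}"))
    return issues
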