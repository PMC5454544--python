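"""From raw trace to a uniformly sampled, baseline-referenced pitch series.

The direct FRT variables are all read off the pitch (forward-lean) angle
of the device.  This module resamples a raw trace onto a uniform grid,
optionally low-pass filters channels with a zero-phase filter, and
derives the pitch displacement series either from the recorder's
attitude output (preferred, passed through untouched) or from the
gravity direction seen by the accelerometer during a quasi-static reach.

The baseline posture is estimated as the mean pitch over an initial
quiet window (the test starts from a held upright stance) and
subtracted, so a forward reach is a positive excursion from ~0 deg.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import (
    InsufficientSamples,
    InvalidCutoff,
    NoUsableChannels,
    QuietWindowTooShort,
)
from .sensor_io import SensorTrace

#: Default cutoff (Hz) for smoothing raw accelerometer channels before the
#: gravity-tilt estimate.  Reach movements last 11-23 s, so their spectral
#: content sits far below 2 Hz.
DEFAULT_CUTOFF_HZ = 2.0

#: Cutoff (Hz) recommended for denoising a pitch series before event
#: detection (see segmentation).  The reach cycle fundamental is ~0.06 Hz;
#: 0.3 Hz keeps the trajectory intact while suppressing wide-band attitude
#: noise enough to localise the peak sample.
EVENT_CUTOFF_HZ = 0.3

DEFAULT_QUIET_WINDOW_S = 0.5

#: Device-frame axis roles for the mounted phone (flat on the back, long
#: axis head-to-foot): index of (forward, vertical, lateral) within the
#: (x, y, z) acceleration columns.
AXIS_CONVENTIONS: dict[str, tuple[int, int, int]] = {
    "flat_back": (2, 1, 0),  # forward=z, vertical=y, lateral=x
}


@dataclass(frozen=True)
class PitchSeries:
    """Uniformly sampled pitch displacement (deg) relative to baseline.

    Sample ``k`` is at time ``t0 + k/rate``.  ``baseline_deg`` is the
    constant already subtracted from the raw pitch.
    """

    rate: float
    t0: float
    values: np.ndarray
    baseline_deg: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def n(self) -> int:
        return int(self.values.shape[0])

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate

    def time_at(self, index: int) -> float:
        return self.t0 + index / self.rate

    def replace(self, **kw) -> "PitchSeries":
        return dataclasses.replace(self, **kw)


def resample_uniform(trace: SensorTrace, rate: float) -> SensorTrace:
    """Linearly interpolate every channel onto a uniform grid at ``rate``.

    The grid spans the input time range; a trace already uniform at the
    target rate is returned with unchanged values.
    """
    if trace.n_samples < 2:
        raise InsufficientSamples(
            f"resampling needs >= 2 samples, got {trace.n_samples}"
        )
    if rate <= 0:
        raise InvalidCutoff(f"rate must be positive, got {rate}")
    t = trace.t
    n_out = int(np.floor((t[-1] - t[0]) * rate + 1e-9)) + 1
    grid = t[0] + np.arange(n_out) / rate

    def _interp(block):
        if block is None:
            return None
        return np.column_stack([np.interp(grid, t, block[:, j]) for j in range(3)])

    return trace.replace(
        t=grid,
        acc=_interp(trace.acc),
        gyro=_interp(trace.gyro),
        attitude=_interp(trace.attitude),
        nominal_rate=float(rate),
    )


def lowpass_smooth(values: np.ndarray, cutoff: float, rate: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass of a uniform scalar signal.

    Applied forward and backward (no phase lag), so event timing is
    preserved; constant signals pass through unchanged.
    """
    if not (0.0 < cutoff < rate / 2.0):
        raise InvalidCutoff(
            f"cutoff must lie in (0, rate/2) = (0, {rate / 2}), got {cutoff}"
        )
    values = np.asarray(values, dtype=float)
    sos = butter(4, cutoff, btype="low", fs=rate, output="sos")
    padlen = min(3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(),
                                                 (sos[:, 5] == 0).sum())),
                 values.shape[0] - 1)
    return sosfiltfilt(sos, values, padlen=max(padlen, 0))


def _check_uniform(trace: SensorTrace) -> float:
    dt = np.diff(trace.t)
    if dt.size == 0:
        raise InsufficientSamples("pitch derivation needs >= 2 samples")
    step = 1.0 / trace.nominal_rate
    if np.max(np.abs(dt - step)) > 1e-6 * max(step, 1.0):
        raise InsufficientSamples(
            "trace is not uniformly sampled at its nominal rate; "
            "run resample_uniform first"
        )
    return trace.nominal_rate


def derive_pitch(
    trace: SensorTrace,
    *,
    pitch_source: str = "auto",
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    quiet_window_s: float = DEFAULT_QUIET_WINDOW_S,
    forward_sign: float = 1.0,
    axis_convention: str = "flat_back",
) -> PitchSeries:
    """Baseline-referenced pitch displacement series from a uniform trace.

    With attitude channels present (``pitch_source`` 'auto' or
    'attitude') the recorded pitch is used directly.  Otherwise the pitch
    is the gravity tilt seen by the (smoothed) accelerometer: the arc
    tangent of the forward gravity component over the magnitude of the
    other two.  The mean over the initial quiet window is subtracted as
    the baseline posture.
    """
    if pitch_source not in ("auto", "attitude", "accelerometer"):
        raise ValueError(f"unknown pitch_source {pitch_source!r}")
    rate = _check_uniform(trace)

    use_attitude = trace.attitude is not None and pitch_source in ("auto", "attitude")
    if pitch_source == "attitude" and trace.attitude is None:
        raise NoUsableChannels("pitch_source='attitude' but trace has no attitude")
    if use_attitude:
        pitch_raw = trace.attitude[:, 0].astype(float)
    else:
        if trace.acc is None:
            raise NoUsableChannels(
                "trace has neither attitude nor acceleration channels"
            )
        ifwd, ivert, ilat = AXIS_CONVENTIONS[axis_convention]
        acc_s = np.column_stack(
            [lowpass_smooth(trace.acc[:, j], cutoff_hz, rate) for j in range(3)]
        )
        fwd = acc_s[:, ifwd]
        rest = np.hypot(acc_s[:, ilat], acc_s[:, ivert])
        pitch_raw = np.degrees(np.arctan2(fwd, rest))

    pitch_raw = forward_sign * pitch_raw
    n_quiet = int(round(quiet_window_s * rate))
    if n_quiet < 2 or n_quiet > pitch_raw.shape[0]:
        raise QuietWindowTooShort(
            f"quiet window of {quiet_window_s} s holds {n_quiet} samples "
            f"(need >= 2 and <= {pitch_raw.shape[0]})"
        )
    baseline = float(np.mean(pitch_raw[:n_quiet]))
    return PitchSeries(
        rate=rate,
        t0=float(trace.t[0]),
        values=pitch_raw - baseline,
        baseline_deg=baseline,
    )


def smooth_pitch(series: PitchSeries, cutoff_hz: float = EVENT_CUTOFF_HZ) -> PitchSeries:
    """Low-pass a pitch series for event detection (zero phase).

    Use before segmenting noisy attitude recordings; noise-free series
    should be segmented unsmoothed.
    """
    return series.replace(values=lowpass_smooth(series.values, cutoff_hz, series.rate))


def refine_baseline(pitch: PitchSeries, events, rest_margin_fraction: float = 0.25,
                    min_rest_samples: int = 8) -> PitchSeries:
    """Re-reference the series to the rest posture around detected events.

    The first-pass baseline comes from a short initial quiet window and
    carries its sampling noise into every threshold crossing.  Once a
    reach has been segmented, everything well before onset and well
    after the return is rest, and its mean is a far better baseline
    estimate.  The onset threshold sits a little way up the rise, so a
    margin of ``rest_margin_fraction`` of the adjacent interval duration
    is excluded on each side (the pre-threshold part of a smooth rise
    spans well under a quarter of the rise).  Returns the re-referenced
    series (identical to the input when the rest already averages to
    zero); left untouched when fewer than ``min_rest_samples`` rest
    samples exist.
    """
    t = pitch.times
    before = events.t_A - rest_margin_fraction * (events.t_B - events.t_A)
    after = events.t_C + rest_margin_fraction * (events.t_C - events.t_B)
    rest = (t <= before) | (t >= after)
    if int(rest.sum()) < min_rest_samples:
        return pitch
    delta = float(pitch.values[rest].mean())
    return pitch.replace(values=pitch.values - delta,
                         baseline_deg=pitch.baseline_deg + delta)
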