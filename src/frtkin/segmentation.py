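"""Detection of the A/B/C phase events of one functional reach.

A reach is read off the baseline-referenced pitch series as three
instants: A, the movement onset; B, the instant of maximum angular
displacement; C, the return to the initial posture.  B is the first
sample attaining the global maximum; A and C are the last/first samples
at or below a threshold set at a fixed fraction of the peak (relative
thresholds generalise across subjects with very different amplitudes).
C must stay below the threshold for a hold period, so a brief noise dip
during the return does not end the movement early.

Recordings with several repetitions are split into candidate excursions
and the repetition with the widest reach is the one analysed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from typing import Optional

from .errors import NoMovementDetected, NoReturnDetected
from .preprocess import PitchSeries, refine_baseline, smooth_pitch


@dataclass(frozen=True)
class SegmentationParams:
    """Detection thresholds.

    onset_fraction
        A and C threshold as a fraction of the detected peak (relative,
        in (0, 0.5)).
    min_peak_deg
        Smallest peak accepted as a movement, in degrees.
    hold_s
        Time the series must stay below threshold to confirm C.
    allow_clamp
        If the record ends mid-return, clamp C to the last sample
        instead of raising NoReturnDetected.
    """

    onset_fraction: float = 0.05
    min_peak_deg: float = 3.0
    hold_s: float = 0.25
    allow_clamp: bool = False

    def validate(self) -> None:
        if not (0.0 < self.onset_fraction < 0.5):
            raise ValueError(
                f"onset_fraction must lie in (0, 0.5), got {self.onset_fraction}"
            )
        if not self.min_peak_deg > 0:
            raise ValueError(f"min_peak_deg must be > 0, got {self.min_peak_deg}")
        if self.hold_s < 0:
            raise ValueError(f"hold_s must be >= 0, got {self.hold_s}")


@dataclass(frozen=True)
class PhaseEvents:
    """The detected A/B/C instants of one reach on a pitch series grid."""

    i_A: int
    i_B: int
    i_C: int
    t_A: float
    t_B: float
    t_C: float
    peak_deg: float


def _confirmed_return(values: np.ndarray, start: int, thr: float, n_hold: int) -> int | None:
    """First index >= start at/below thr that stays there for n_hold
    samples (a run reaching the end of the record counts as sustained)."""
    n = values.shape[0]
    i = start
    while i < n:
        if values[i] <= thr:
            j = min(i + n_hold, n - 1)
            if np.all(values[i : j + 1] <= thr):
                return i
            # skip past the first re-crossing inside the failed window
            above = i + 1 + int(np.argmax(values[i + 1 : j + 1] > thr))
            i = above + 1
        else:
            i += 1
    return None


def _events_around_peak(
    pitch: PitchSeries, i_B: int, peak: float, params: SegmentationParams
) -> PhaseEvents:
    v = pitch.values
    thr = params.onset_fraction * peak

    below_before = np.nonzero(v[:i_B] <= thr)[0]
    if below_before.size == 0:
        raise NoMovementDetected(
            "series never starts at rest: no sample at or below the onset "
            "threshold before the peak"
        )
    i_A = int(below_before[-1])

    n_hold = int(round(params.hold_s * pitch.rate))
    i_C = _confirmed_return(v, i_B + 1, thr, n_hold)
    if i_C is None:
        if params.allow_clamp and i_B < pitch.n - 1:
            i_C = pitch.n - 1
        else:
            raise NoReturnDetected(
                "series does not settle back below the onset threshold "
                "after the peak (recording ends mid-return?)"
            )
    return PhaseEvents(
        i_A=i_A,
        i_B=i_B,
        i_C=int(i_C),
        t_A=pitch.time_at(i_A),
        t_B=pitch.time_at(i_B),
        t_C=pitch.time_at(int(i_C)),
        peak_deg=float(peak),
    )


def detect_events(
    pitch: PitchSeries, params: SegmentationParams | None = None
) -> PhaseEvents:
    """Detect A/B/C for a single-reach pitch series.

    B is the first sample attaining the global maximum; A is the last
    sample before B at or below ``onset_fraction * peak``; C is the
    first sample after B at or below that threshold that stays below it
    for ``hold_s`` seconds.
    """
    params = params or SegmentationParams()
    params.validate()
    v = pitch.values
    if v.size == 0:
        raise NoMovementDetected("empty series")
    i_B = int(np.argmax(v))
    peak = float(v[i_B])
    if peak < params.min_peak_deg:
        raise NoMovementDetected(
            f"maximum pitch displacement {peak:.2f} deg is below "
            f"min_peak_deg={params.min_peak_deg}"
        )
    return _events_around_peak(pitch, i_B, peak, params)


def _excursions(v: np.ndarray, thr: float) -> list[tuple[int, int]]:
    """Maximal runs of samples strictly above thr, as (start, stop) inclusive."""
    above = v > thr
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    stops = list(np.nonzero(edges == -1)[0])
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(v.shape[0] - 1)
    return list(zip(starts, stops))


def select_widest(
    pitch: PitchSeries, params: SegmentationParams | None = None
) -> PhaseEvents:
    """Events of the repetition with the widest reach.

    The series is partitioned into maximal excursions above the onset
    threshold (relative to the global maximum); the excursion with the
    largest peak wins, ties going to the earliest.  Each excursion is
    then segmented exactly as :func:`detect_events` would segment it in
    isolation, with the threshold relative to its own peak.
    """
    params = params or SegmentationParams()
    params.validate()
    v = pitch.values
    if v.size == 0:
        raise NoMovementDetected("empty series")
    global_peak = float(v.max())
    if global_peak < params.min_peak_deg:
        raise NoMovementDetected(
            f"maximum pitch displacement {global_peak:.2f} deg is below "
            f"min_peak_deg={params.min_peak_deg}"
        )
    runs = _excursions(v, params.onset_fraction * global_peak)
    best: tuple[float, int, int] | None = None  # (peak, i_B, order)
    for order, (s, e) in enumerate(runs):
        i_B = s + int(np.argmax(v[s : e + 1]))
        peak = float(v[i_B])
        if peak < params.min_peak_deg:
            continue
        if best is None or peak > best[0]:  # strict: ties keep the earlier run
            best = (peak, i_B, order)
    if best is None:
        raise NoMovementDetected(
            f"no excursion exceeds min_peak_deg={params.min_peak_deg}"
        )
    peak, i_B, _ = best
    return _events_around_peak(pitch, i_B, peak, params)


def segment_reach(
    pitch: PitchSeries,
    params: SegmentationParams | None = None,
    *,
    smooth_hz: Optional[float] = None,
    widest: bool = True,
    refine: bool = True,
    rest_margin_fraction: float = 0.25,
) -> tuple[PitchSeries, PhaseEvents]:
    """Full segmentation of one recording: smooth, detect, re-baseline,
    re-detect.

    ``smooth_hz`` applies zero-phase event-band smoothing first (pass
    None for clean series).  With ``refine`` the baseline is
    re-estimated from all rest samples identified by the first pass and
    the events detected again — on noisy recordings this stabilises the
    threshold crossings considerably; on clean series it is a no-op.
    Returns the series the events were detected on, ready for
    kinematics.
    """
    params = params or SegmentationParams()
    pick = select_widest if widest else detect_events

    def _prepared(series: PitchSeries) -> PitchSeries:
        return smooth_pitch(series, smooth_hz) if smooth_hz else series

    used = _prepared(pitch)
    events = pick(used, params)
    if refine:
        rebased = refine_baseline(pitch, events, rest_margin_fraction)
        used = _prepared(rebased)
        events = pick(used, params)
    return used, events
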