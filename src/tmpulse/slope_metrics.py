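"""Slope-ratio computation: per pulse, per 10-second window, per recording.

The slope ratio (SR) of a pulse is its downslope divided by its upslope,
where both slopes are two-point secants between fiducials:

    upslope   = (peak - foot) / (t_peak - t_foot)        (> 0)
    downslope = (end - peak) / (t_end - t_peak)          (< 0)
    SR        = downslope / upslope                      (< 0)

SR is dimensionless and invariant to adding a constant to the pressure, to
positive amplitude scaling, and to positive time rescaling — which is what
makes it usable on a sensor with an uncalibrated, ear-dependent gain.  A
recording's SR is the mean over non-overlapping 10-second windows of the
per-window mean pulse SR.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pulse_processing import Pulse
from .trace import Segment

__all__ = [
    "PulseFeatures",
    "FlaggedPulse",
    "WindowSR",
    "RecordingSR",
    "UnanalyzableRecording",
    "PulseRejected",
    "compute_slopes",
    "extract_features",
    "window_average",
    "summarize_recording",
]

DEFAULT_WINDOW_S = 10.0
DEFAULT_MIN_PULSES = 3


class PulseRejected(ValueError):
    """A pulse whose slopes cannot be computed (zero duration, flat rise)."""


class UnanalyzableRecording(ValueError):
    """Recording with no surviving analysis window; distinct from any class."""


@dataclass(frozen=True)
class PulseFeatures:
    upslope: float
    downslope: float
    slope_ratio: float


@dataclass(frozen=True)
class FlaggedPulse:
    pulse: Pulse
    reason: str


def compute_slopes(pulse: Pulse) -> PulseFeatures:
    """Secant upslope/downslope and their ratio for one pulse.

    Raises :class:`PulseRejected` for zero rise/fall durations or a
    non-positive upslope; callers exclude such pulses downstream.
    """
    rise_t = pulse.peak_time - pulse.foot_time
    fall_t = pulse.end_time - pulse.peak_time
    if rise_t <= 0:
        raise PulseRejected(f"zero rise duration at foot index {pulse.foot_index}")
    if fall_t <= 0:
        raise PulseRejected(f"zero fall duration at peak index {pulse.peak_index}")
    upslope = (pulse.peak_value - pulse.foot_value) / rise_t
    downslope = (pulse.end_value - pulse.peak_value) / fall_t
    if upslope <= 0:
        raise PulseRejected(f"non-positive upslope at foot index {pulse.foot_index}")
    return PulseFeatures(
        upslope=upslope, downslope=downslope, slope_ratio=downslope / upslope
    )


def extract_features(
    pulses: list[Pulse],
) -> tuple[list[tuple[Pulse, PulseFeatures]], list[FlaggedPulse]]:
    """Compute slopes for a batch, separating rejected pulses with reasons."""
    kept: list[tuple[Pulse, PulseFeatures]] = []
    flagged: list[FlaggedPulse] = []
    for p in pulses:
        try:
            kept.append((p, compute_slopes(p)))
        except PulseRejected as exc:
            flagged.append(FlaggedPulse(pulse=p, reason=str(exc)))
    return kept, flagged


@dataclass(frozen=True)
class WindowSR:
    """Mean pulse SR over one fixed-length analysis window."""

    start_s: float
    end_s: float
    mean_sr: float
    n_pulses: int


def window_average(
    features: list[tuple[Pulse, PulseFeatures]],
    window_s: float = DEFAULT_WINDOW_S,
    min_pulses: int = DEFAULT_MIN_PULSES,
    segments: list[Segment] | None = None,
) -> list[WindowSR]:
    """Tile non-overlapping windows and average member-pulse SRs.

    Windows are anchored at the first pulse's peak time and a pulse belongs
    to the window containing its peak.  When maneuver ``segments`` are given,
    windows are tiled independently inside each segment so none straddles a
    maneuver boundary.  Windows with fewer than ``min_pulses`` pulses are
    dropped.
    """
    if window_s <= 0:
        raise ValueError(f"window_s must be positive, got {window_s}")
    if min_pulses < 1:
        raise ValueError(f"min_pulses must be >= 1, got {min_pulses}")
    if not features:
        return []
    if segments:
        out: list[WindowSR] = []
        for seg in segments:
            inside = [
                (p, f) for p, f in features if seg.start_s <= p.peak_time < seg.end_s
            ]
            out.extend(_tile_windows(inside, window_s, min_pulses))
        return out
    return _tile_windows(features, window_s, min_pulses)


def _tile_windows(
    features: list[tuple[Pulse, PulseFeatures]], window_s: float, min_pulses: int
) -> list[WindowSR]:
    if not features:
        return []
    t0 = min(p.peak_time for p, _ in features)
    buckets: dict[int, list[float]] = {}
    for p, f in features:
        k = int((p.peak_time - t0) // window_s)
        buckets.setdefault(k, []).append(f.slope_ratio)
    windows = []
    for k in sorted(buckets):
        srs = buckets[k]
        if len(srs) < min_pulses:
            continue
        windows.append(
            WindowSR(
                start_s=t0 + k * window_s,
                end_s=t0 + (k + 1) * window_s,
                mean_sr=float(np.mean(srs)),
                n_pulses=len(srs),
            )
        )
    return windows


@dataclass(frozen=True)
class RecordingSR:
    """Per-recording SR summary: unweighted mean of window means."""

    recording_id: str
    state: str | None
    sr: float
    n_windows: int


def summarize_recording(
    windows: list[WindowSR], recording_id: str, state: str | None = None
) -> RecordingSR:
    """Collapse surviving windows to the recording-level SR.

    Raises :class:`UnanalyzableRecording` when no window survived, so an
    unmeasurable recording can never silently become a classification.
    """
    if not windows:
        raise UnanalyzableRecording(
            f"recording {recording_id!r} has no analysis window with enough pulses"
        )
    return RecordingSR(
        recording_id=recording_id,
        state=state,
        sr=float(np.mean([w.mean_sr for w in windows])),
        n_windows=len(windows),
    )
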