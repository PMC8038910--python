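"""Trace conditioning and cardiac-pulse segmentation.

The recorded TMP signal carries slow postural/respiratory drift under the
cardiac pulse train.  ``preprocess`` removes it with a zero-phase Butterworth
band-pass (phase distortion would bias the rise/fall asymmetry the slope
ratio measures).  ``detect_pulses`` then segments the trace into pulses:
dominant peaks are prominence-gated local maxima, the foot of each pulse is
the global minimum since the previous peak, and pulse *i* ends at the foot of
pulse *i+1*, so detected pulses tile the covered span.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .trace import SignalTrace

__all__ = ["Pulse", "preprocess", "detect_pulses"]

DEFAULT_BAND = (0.3, 20.0)
DEFAULT_MIN_INTERVAL_S = 0.33
DEFAULT_PROMINENCE_FRAC = 0.3


@dataclass(frozen=True)
class Pulse:
    """One segmented cardiac pulse: foot -> dominant peak -> end fiducials.

    The end fiducial of pulse *i* is the foot of pulse *i+1*.  Indices are
    0-based samples; times in seconds; values in the trace's pressure units.
    """

    foot_index: int
    peak_index: int
    end_index: int
    foot_time: float
    peak_time: float
    end_time: float
    foot_value: float
    peak_value: float
    end_value: float
    state: str | None = None

    def __post_init__(self) -> None:
        if not self.foot_index < self.peak_index < self.end_index:
            raise ValueError(
                f"fiducials must satisfy foot < peak < end, got "
                f"({self.foot_index}, {self.peak_index}, {self.end_index})"
            )
        if not (self.peak_value > self.foot_value and self.peak_value > self.end_value):
            raise ValueError("peak_value must exceed both foot_value and end_value")


def preprocess(
    trace: SignalTrace, band: tuple[float, float] = DEFAULT_BAND, order: int = 4
) -> SignalTrace:
    """Zero-phase Butterworth band-pass; annotations and length preserved.

    Forward-backward filtering (``sosfiltfilt``) guarantees no group delay,
    so fiducial times are not shifted.  A zero low edge degrades gracefully
    to a pure low-pass.
    """
    low, high = band
    nyquist = trace.sampling_rate / 2.0
    if not (0 <= low < high < nyquist):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 <= low < high < "
            f"Nyquist ({nyquist:g} Hz)"
        )
    if low == 0:
        sos = sps.butter(order, high, btype="lowpass", output="sos", fs=trace.sampling_rate)
    else:
        sos = sps.butter(
            order, (low, high), btype="bandpass", output="sos", fs=trace.sampling_rate
        )
    filtered = sps.sosfiltfilt(sos, trace.samples)
    return SignalTrace(
        samples=filtered,
        sampling_rate=trace.sampling_rate,
        segments=list(trace.segments),
    )


def detect_pulses(
    trace: SignalTrace,
    min_interval: float = DEFAULT_MIN_INTERVAL_S,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
) -> list[Pulse]:
    """Segment a conditioned trace into complete cardiac pulses.

    Dominant peaks are local maxima at least ``min_interval`` apart whose
    prominence reaches ``prominence_frac`` times the median prominence of all
    candidate maxima.  Feet are inter-peak global minima (earliest sample on
    ties); the final peak, lacking a following foot, is discarded.  Detected
    indices are invariant to positive amplitude scaling of the trace.
    """
    if min_interval <= 0:
        raise ValueError(f"min_interval must be positive, got {min_interval}")
    x = trace.samples
    fs = trace.sampling_rate
    if x.shape[0] < 2 * min_interval * fs:
        return []
    if np.ptp(x) == 0:
        return []
    distance = max(1, int(round(min_interval * fs)))
    candidates, props = sps.find_peaks(x, distance=distance, prominence=0.0)
    if candidates.shape[0] < 2:
        return []
    prominences = props["prominences"]
    threshold = prominence_frac * float(np.median(prominences))
    peaks = candidates[prominences >= threshold]
    if peaks.shape[0] < 2:
        return []
    feet = np.empty(peaks.shape[0], dtype=int)
    lo = 0
    for i, p in enumerate(peaks):
        feet[i] = lo + int(np.argmin(x[lo:p]))  # argmin -> earliest tie
        lo = p
    pulses: list[Pulse] = []
    for i in range(peaks.shape[0] - 1):
        f, p, e = int(feet[i]), int(peaks[i]), int(feet[i + 1])
        if not (x[p] > x[f] and x[p] > x[e]):
            continue  # degenerate (flat) region
        pulses.append(
            Pulse(
                foot_index=f,
                peak_index=p,
                end_index=e,
                foot_time=f / fs,
                peak_time=p / fs,
                end_time=e / fs,
                foot_value=float(x[f]),
                peak_value=float(x[p]),
                end_value=float(x[e]),
                state=trace.label_at(f / fs),
            )
        )
    return pulses
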