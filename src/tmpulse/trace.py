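"""Shared containers for uniformly sampled pressure traces.

A :class:`SignalTrace` is the unit every stage of the pipeline exchanges:
the simulator emits one, the preprocessing filter returns a new one, and the
pulse detector consumes one.  Maneuver annotations ride along as half-open
``[start_s, end_s)`` segments so windowing never straddles a maneuver
boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Segment", "SignalTrace"]


@dataclass(frozen=True)
class Segment:
    """One maneuver annotation: half-open interval ``[start_s, end_s)``."""

    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError(
                f"segment {self.label!r}: end_s ({self.end_s}) must exceed "
                f"start_s ({self.start_s})"
            )

    def contains(self, t: float) -> bool:
        return self.start_s <= t < self.end_s

    def to_dict(self) -> dict:
        return {"label": self.label, "start_s": self.start_s, "end_s": self.end_s}

    @classmethod
    def from_dict(cls, d: dict) -> "Segment":
        return cls(label=d["label"], start_s=float(d["start_s"]), end_s=float(d["end_s"]))


@dataclass
class SignalTrace:
    """Uniformly sampled single-channel pressure series.

    Parameters
    ----------
    samples
        Pressure in arbitrary sensor units, one value per sample.
    sampling_rate
        Samples per second (Hz), strictly positive.
    segments
        Optional, non-overlapping maneuver annotations sorted by start time,
        all lying within the trace duration.
    """

    samples: np.ndarray
    sampling_rate: float
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if not self.sampling_rate > 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        self.segments = sorted(self.segments, key=lambda s: s.start_s)
        dur = self.duration_s
        prev_end = 0.0
        for seg in self.segments:
            if seg.start_s < prev_end - 1e-9:
                raise ValueError(f"segments overlap at {seg.label!r} ({seg.start_s} s)")
            if seg.end_s > dur + 1e-9:
                raise ValueError(
                    f"segment {seg.label!r} ends at {seg.end_s} s, beyond the "
                    f"trace duration {dur:.6g} s"
                )
            prev_end = seg.end_s

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Time axis in seconds, starting at 0 with fixed step 1/rate."""
        return np.arange(self.n_samples) / self.sampling_rate

    def label_at(self, t: float) -> str | None:
        """Maneuver label covering time ``t`` (half-open), or None."""
        for seg in self.segments:
            if seg.contains(t):
                return seg.label
        return None
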