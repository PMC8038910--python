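"""Synthetic tympanic-membrane-pulsation (TMP) waveform generator.

The intracranial pressure (ICP) cardiac pulse reaches the tympanic membrane
through the cochlear aqueduct; its morphology carries the classic P1
(percussion), P2 (tidal) and P3 (dicrotic) sub-peaks.  With reduced
intracranial compliance (elevated ICP) the pulse rise time lengthens and the
dominant peak shifts toward the end of the cardiac cycle, which drives the
slope-ratio statistic downward.  This module renders such pulses from an
explicit parametric template so that every generated trace comes with exact
ground-truth fiducials and a known template slope ratio.

Template model
--------------
Each cardiac cycle is a piecewise-linear rise--fall envelope (pulse foot ->
dominant peak at ``rise_fraction`` of the cycle -> foot) with up to three
Gaussian sub-peaks superimposed.  For the bare envelope the slope ratio has
the closed form ``SR(r) = -r / (1 - r)``, so the simulator's ground truth is
analytically checkable.  Maneuver states (upright baseline, 45-degree
head-down tilt, hyperventilation, recovery) differ in their morphology
parameter distributions; the head-down tilt state models elevated ICP with a
larger rise fraction and a tidal-peak-dominant sub-peak pattern.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .trace import Segment, SignalTrace

__all__ = [
    "STATE_LABELS",
    "DEFAULT_STATE_DURATIONS",
    "PulseMorphology",
    "MorphologyDistribution",
    "IcpState",
    "ManeuverSchedule",
    "SimulationConfig",
    "GroundTruth",
    "CohortRecording",
    "default_state_params",
    "render_pulse",
    "triangular_slope_ratio",
    "simulate_recording",
    "simulate_cohort",
]

#: Canonical maneuver states in protocol order.
STATE_LABELS = ("upright_baseline", "head_down_tilt", "hyperventilation", "recovery")

#: Per-state recording durations in seconds.  Baselines and recovery are the
#: protocol's two-minute rest recordings; the tilt maneuver lasts 30 s.  The
#: hyperventilation duration is a package choice (60 s) because the protocol
#: does not fix one.
DEFAULT_STATE_DURATIONS = {
    "upright_baseline": 120.0,
    "head_down_tilt": 30.0,
    "hyperventilation": 60.0,
    "recovery": 120.0,
}

_STATE_TRUTH = {
    "upright_baseline": "normal",
    "head_down_tilt": "elevated",
    "hyperventilation": "normal",
    "recovery": "normal",
}


def triangular_slope_ratio(rise_fraction: float) -> float:
    """Closed-form slope ratio of a triangular pulse, ``-r / (1 - r)``.

    Strictly decreasing in ``r`` on (0, 1): a later dominant peak (delayed
    rise, the elevated-ICP signature) gives a more negative slope ratio.
    """
    r = float(rise_fraction)
    if not 0.0 < r < 1.0:
        raise ValueError(f"rise_fraction must lie in (0, 1), got {r}")
    return -r / (1.0 - r)


@dataclass(frozen=True)
class PulseMorphology:
    """Parametric shape of one cardiac TMP pulse.

    All latencies and widths are fractions of the cardiac cycle; amplitudes
    are in arbitrary pressure units.  ``rise_fraction`` places the envelope's
    dominant peak; the three Gaussian bumps render the P1/P2/P3 sub-peaks.
    """

    peak_latencies: tuple[float, float, float]
    peak_amplitudes: tuple[float, float, float]
    peak_widths: tuple[float, float, float]
    rise_fraction: float
    envelope_amplitude: float = 1.0

    def __post_init__(self) -> None:
        lat = tuple(float(v) for v in self.peak_latencies)
        amp = tuple(float(v) for v in self.peak_amplitudes)
        wid = tuple(float(v) for v in self.peak_widths)
        if len(lat) != 3 or len(amp) != 3 or len(wid) != 3:
            raise ValueError("peak_latencies, peak_amplitudes and peak_widths need 3 entries each")
        if not (0.0 < lat[0] < lat[1] < lat[2] < 1.0):
            raise ValueError(
                f"peak_latencies must be strictly increasing within (0, 1), got {lat}"
            )
        if any(a < 0 for a in amp):
            raise ValueError(f"peak_amplitudes must be nonnegative, got {amp}")
        if any(w <= 0 for w in wid):
            raise ValueError(f"peak_widths must be positive, got {wid}")
        if not 0.0 < self.rise_fraction < 1.0:
            raise ValueError(f"rise_fraction must lie in (0, 1), got {self.rise_fraction}")
        if self.envelope_amplitude < 0:
            raise ValueError(f"envelope_amplitude must be nonnegative, got {self.envelope_amplitude}")
        object.__setattr__(self, "peak_latencies", lat)
        object.__setattr__(self, "peak_amplitudes", amp)
        object.__setattr__(self, "peak_widths", wid)


def render_pulse(
    morphology: PulseMorphology, cycle_length: float, sampling_rate: float
) -> np.ndarray:
    """Render one cardiac cycle, foot to foot, as a sampled waveform.

    The returned array covers ``[0, cycle_length)``; the first sample is the
    pulse foot and the (excluded) endpoint is the next pulse's foot.  The
    envelope peak lands at ``rise_fraction * cycle_length`` within one sample.
    A morphology with all amplitudes zero renders a flat cycle.
    """
    if cycle_length <= 0:
        raise ValueError(f"cycle_length must be positive, got {cycle_length}")
    n = int(round(cycle_length * sampling_rate))
    if n < 10:
        raise ValueError(
            f"cycle too short: {n} samples at {sampling_rate} Hz (need >= 10)"
        )
    frac = np.arange(n) / n  # fraction of the cycle, in [0, 1)
    r = morphology.rise_fraction
    envelope = np.where(frac <= r, frac / r, (1.0 - frac) / (1.0 - r))
    out = morphology.envelope_amplitude * envelope
    for lat, amp, wid in zip(
        morphology.peak_latencies, morphology.peak_amplitudes, morphology.peak_widths
    ):
        if amp > 0:
            out = out + amp * np.exp(-0.5 * ((frac - lat) / wid) ** 2)
    return out


def _template_slope_ratio(cycle: np.ndarray, sampling_rate: float) -> float:
    """Secant slope ratio of a rendered noise-free cycle.

    Upslope: foot (sample 0) to the cycle argmax.  Downslope: argmax to the
    next pulse foot (the envelope returns to 0 at the excluded endpoint).
    Equals ``-r/(1-r)`` exactly for a bare envelope whose peak lands on a
    sample.
    """
    n = cycle.shape[0]
    peak = int(np.argmax(cycle))
    if peak == 0:
        return math.nan
    up = (cycle[peak] - cycle[0]) * sampling_rate / peak
    down = (0.0 - cycle[peak]) * sampling_rate / (n - peak)
    return down / up


@dataclass
class MorphologyDistribution:
    """Pulse-to-pulse distribution of morphology parameters within a state.

    ``mean`` holds the state's central morphology; the SD fields add
    independent Gaussian jitter per pulse, truncated so every draw remains a
    valid :class:`PulseMorphology`.
    """

    mean: PulseMorphology
    rise_fraction_sd: float = 0.01
    latency_sd: float = 0.004
    amplitude_sd: float = 0.01
    width_sd: float = 0.0
    envelope_amplitude_cv: float = 0.02

    def __post_init__(self) -> None:
        for name in ("rise_fraction_sd", "latency_sd", "amplitude_sd", "width_sd",
                     "envelope_amplitude_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def sample(self, rng: np.random.Generator) -> PulseMorphology:
        m = self.mean
        r = float(np.clip(
            m.rise_fraction + self.rise_fraction_sd * rng.standard_normal(),
            0.10, 0.985,
        ))
        lat = np.sort(
            np.asarray(m.peak_latencies) + self.latency_sd * rng.standard_normal(3)
        )
        lat = np.clip(lat, 0.02, 0.95)
        # keep strict ordering after clipping
        for i in (1, 2):
            if lat[i] <= lat[i - 1]:
                lat[i] = lat[i - 1] + 1e-3
        amp = np.clip(
            np.asarray(m.peak_amplitudes) + self.amplitude_sd * rng.standard_normal(3),
            0.0, None,
        )
        wid = np.clip(
            np.asarray(m.peak_widths) + self.width_sd * rng.standard_normal(3),
            1e-3, None,
        )
        env = m.envelope_amplitude * max(
            0.1, 1.0 + self.envelope_amplitude_cv * rng.standard_normal()
        )
        return PulseMorphology(
            peak_latencies=tuple(lat),
            peak_amplitudes=tuple(amp),
            peak_widths=tuple(wid),
            rise_fraction=r,
            envelope_amplitude=env,
        )


@dataclass
class IcpState:
    """A maneuver state: its morphology distribution and ground-truth class."""

    label: str
    morphology: MorphologyDistribution
    truth_class: str

    def __post_init__(self) -> None:
        if self.label not in STATE_LABELS:
            raise ValueError(f"unknown state label {self.label!r}")
        if self.truth_class not in ("normal", "elevated"):
            raise ValueError(f"truth_class must be normal/elevated, got {self.truth_class!r}")
        if self.label == "head_down_tilt" and self.truth_class != "elevated":
            raise ValueError("head_down_tilt must map to truth_class 'elevated'")
        if self.label != "head_down_tilt" and self.truth_class != "normal":
            raise ValueError(f"{self.label} must map to truth_class 'normal'")


def default_state_params() -> dict[str, IcpState]:
    """Default per-state morphology distributions.

    Rise-fraction means: baseline/recovery 0.60, head-down tilt 0.85 (delayed
    rise and right-shifted dominant peak, the elevated-ICP signature),
    hyperventilation 0.57 (hypocapnia lowers ICP below the upright baseline,
    so the rise shortens slightly).  P1/P2/P3 ride the envelope as
    shoulder-scale Gaussian bumps, deliberately below the amplitude at which
    a bump would form its own local maximum on the rising envelope: the
    dominant peak of every rendered pulse is therefore the envelope peak, and
    the pulse detector can never mistake a sub-peak for a beat at any heart
    rate.  Under tilt the tidal (P2) shoulder is emphasized.  Absolute values
    are free parameters; only the orderings are physiologically constrained,
    and the fall (0.4 cycles at baseline) is kept long relative to the
    band-pass impulse response so the measured SR is heart-rate stable.
    """

    def morph(rise: float, amps: tuple[float, float, float]) -> MorphologyDistribution:
        return MorphologyDistribution(
            mean=PulseMorphology(
                peak_latencies=(0.15, 0.45, 0.65),
                peak_amplitudes=amps,
                peak_widths=(0.05, 0.06, 0.06),
                rise_fraction=rise,
                envelope_amplitude=1.0,
            ),
            amplitude_sd=0.005,
        )

    return {
        "upright_baseline": IcpState(
            "upright_baseline", morph(0.60, (0.05, 0.04, 0.03)), "normal"
        ),
        "head_down_tilt": IcpState(
            "head_down_tilt", morph(0.85, (0.03, 0.05, 0.03)), "elevated"
        ),
        "hyperventilation": IcpState(
            "hyperventilation", morph(0.57, (0.05, 0.04, 0.03)), "normal"
        ),
        "recovery": IcpState("recovery", morph(0.60, (0.05, 0.04, 0.03)), "normal"),
    }


@dataclass(frozen=True)
class ManeuverSchedule:
    """Ordered (state label, duration in seconds) protocol segments."""

    segments: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if len(self.segments) == 0:
            raise ValueError("schedule must contain at least one segment")
        segs = tuple((str(label), float(dur)) for label, dur in self.segments)
        for label, dur in segs:
            if label not in STATE_LABELS:
                raise ValueError(f"unknown state label {label!r} in schedule")
            if dur <= 0:
                raise ValueError(f"segment {label!r} has non-positive duration {dur}")
        object.__setattr__(self, "segments", segs)

    @classmethod
    def default(cls) -> "ManeuverSchedule":
        """Full protocol: upright -> head-down tilt -> hyperventilation -> recovery."""
        return cls(tuple((s, DEFAULT_STATE_DURATIONS[s]) for s in STATE_LABELS))

    @classmethod
    def single(cls, label: str, duration: float | None = None) -> "ManeuverSchedule":
        if duration is None:
            duration = DEFAULT_STATE_DURATIONS[label]
        return cls(((label, duration),))

    @property
    def total_duration_s(self) -> float:
        return sum(d for _, d in self.segments)


@dataclass
class SimulationConfig:
    """Everything needed to synthesize one recording reproducibly.

    noise_sd and the respiratory-drift amplitude are fractions of the mean
    pulse (envelope) amplitude.  During hyperventilation segments the
    respiratory frequency switches to ``hyperventilation_resp_frequency``.
    """

    sampling_rate: float = 200.0
    heart_rate_mean: float = 70.0
    heart_rate_subject_sd: float = 5.0
    cycle_jitter_cv: float = 0.02
    noise_sd: float = 0.02
    respiratory_drift: tuple[float, float] = (0.25, 0.10)
    hyperventilation_resp_frequency: float = 0.5
    seed: int = 0
    schedule: ManeuverSchedule = field(default_factory=ManeuverSchedule.default)
    state_params: dict[str, IcpState] = field(default_factory=default_state_params)

    def __post_init__(self) -> None:
        if self.sampling_rate < 50:
            raise ValueError(f"sampling_rate must be >= 50 Hz, got {self.sampling_rate}")
        if not 40 <= self.heart_rate_mean <= 180:
            raise ValueError(f"heart_rate_mean must lie in [40, 180] bpm, got {self.heart_rate_mean}")
        for name in ("heart_rate_subject_sd", "cycle_jitter_cv", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        freq, amp = self.respiratory_drift
        if freq < 0 or amp < 0:
            raise ValueError("respiratory_drift (frequency, amplitude) must be >= 0")
        for label, _ in self.schedule.segments:
            if label not in self.state_params:
                raise ValueError(f"schedule uses state {label!r} with no parameters")


@dataclass
class GroundTruth:
    """Generator-side truth for every complete pulse in a recording.

    ``end_samples[i]`` is the foot of pulse ``i+1`` (for the final pulse, the
    first sample past its cycle).  ``template_sr`` is the secant slope ratio
    of the noise-free rendered cycle.
    """

    foot_samples: np.ndarray
    peak_samples: np.ndarray
    end_samples: np.ndarray
    states: np.ndarray
    template_sr: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.foot_samples)
        for name in ("peak_samples", "end_samples", "states", "template_sr"):
            if len(getattr(self, name)) != n:
                raise ValueError("ground-truth arrays must share one length")
        if n and not (
            np.all(self.foot_samples < self.peak_samples)
            and np.all(self.peak_samples < self.end_samples)
        ):
            raise ValueError("fiducial indices must be strictly increasing per pulse")

    @property
    def n_pulses(self) -> int:
        return len(self.foot_samples)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "pulse_idx": np.arange(self.n_pulses),
                "foot_sample": self.foot_samples,
                "peak_sample": self.peak_samples,
                "end_sample": self.end_samples,
                "state": self.states,
                "template_sr": self.template_sr,
            }
        )


def simulate_recording(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    heart_rate: float | None = None,
    amplitude_scale: float = 1.0,
) -> tuple[SignalTrace, GroundTruth]:
    """Synthesize one annotated recording plus its ground truth.

    Cycles are drawn per maneuver segment with lognormal-free Gaussian cycle
    jitter, concatenated foot-to-foot, then a respiratory sinusoid and white
    Gaussian sensor noise are added.  Identical config and seed give
    bit-identical output.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    if heart_rate is None:
        heart_rate = float(
            np.clip(
                rng.normal(config.heart_rate_mean, config.heart_rate_subject_sd),
                40.0,
                180.0,
            )
        )
    foot, peak, end, states, template = [], [], [], [], []
    chunks: list[np.ndarray] = []
    annotations: list[Segment] = []
    start = 0  # absolute sample index of current segment
    resp_freq, resp_amp = config.respiratory_drift
    for label, duration in config.schedule.segments:
        n_seg = int(round(duration * fs))
        state = config.state_params[label]
        buf = np.zeros(n_seg)
        pos = 0
        while pos < n_seg:
            cycle_len = (60.0 / heart_rate) * max(
                0.5, 1.0 + config.cycle_jitter_cv * rng.standard_normal()
            )
            morph = state.morphology.sample(rng)
            cycle = render_pulse(morph, cycle_len, fs) * amplitude_scale
            nc = cycle.shape[0]
            take = min(nc, n_seg - pos)
            buf[pos : pos + take] = cycle[:take]
            if take == nc:  # complete cycle -> ground-truth pulse
                peak_rel = int(np.argmax(cycle))
                foot.append(start + pos)
                peak.append(start + pos + peak_rel)
                end.append(start + pos + nc)
                states.append(label)
                template.append(_template_slope_ratio(cycle, fs))
            pos += take
        freq = (
            config.hyperventilation_resp_frequency
            if label == "hyperventilation"
            else resp_freq
        )
        if resp_amp > 0 and freq > 0:
            t_seg = (start + np.arange(n_seg)) / fs
            buf += resp_amp * amplitude_scale * np.sin(2.0 * np.pi * freq * t_seg)
        annotations.append(Segment(label, start / fs, (start + n_seg) / fs))
        chunks.append(buf)
        start += n_seg
    samples = np.concatenate(chunks) if chunks else np.zeros(0)
    if config.noise_sd > 0:
        samples = samples + rng.normal(
            0.0, config.noise_sd * amplitude_scale, samples.shape[0]
        )
    trace = SignalTrace(samples=samples, sampling_rate=fs, segments=annotations)
    truth = GroundTruth(
        foot_samples=np.asarray(foot, dtype=int),
        peak_samples=np.asarray(peak, dtype=int),
        end_samples=np.asarray(end, dtype=int),
        states=np.asarray(states, dtype=object),
        template_sr=np.asarray(template, dtype=float),
    )
    return trace, truth


@dataclass
class CohortRecording:
    """One simulated single-maneuver recording with its study metadata."""

    recording_id: str
    subject: int
    round: int
    state: str
    truth_class: str
    counted: bool
    trace: SignalTrace
    ground_truth: GroundTruth


def _subject_physiology(
    config: SimulationConfig, seed: int, subject: int
) -> tuple[float, float]:
    """Heart rate (bpm) and amplitude scale for one subject, drawn once."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7919, subject)))
    hr = float(
        np.clip(
            rng.normal(config.heart_rate_mean, config.heart_rate_subject_sd), 40.0, 180.0
        )
    )
    amp = float(max(0.2, rng.normal(1.0, 0.10)))
    return hr, amp


def simulate_cohort(
    n_subjects: int,
    n_rounds: int,
    config: SimulationConfig | None = None,
    *,
    seed: int = 0,
    counted_states: tuple[str, ...] = (
        "upright_baseline",
        "head_down_tilt",
        "hyperventilation",
    ),
    states: tuple[str, ...] = STATE_LABELS,
    subject_offset: int = 0,
    cohort_label: str = "cohort",
) -> list[CohortRecording]:
    """Simulate a cohort: one recording per (subject, round, state).

    Each subject's heart rate and pulse amplitude are drawn once and reused
    across that subject's rounds.  Every recording gets its own RNG stream
    seeded from (seed, subject, round, state), so cohorts are
    order-independent and held-out cohorts are independent of training ones.
    ``counted`` recordings are the ones the classification study scores
    (recovery is simulated for the maneuver-contrast statistics but not
    counted).
    """
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    if n_rounds < 1:
        raise ValueError(f"n_rounds must be >= 1, got {n_rounds}")
    if config is None:
        config = SimulationConfig(seed=seed)
    unknown = set(counted_states) - set(states)
    if unknown:
        raise ValueError(f"counted_states not in simulated states: {sorted(unknown)}")
    recordings: list[CohortRecording] = []
    for s in range(n_subjects):
        subject = subject_offset + s
        hr, amp = _subject_physiology(config, seed, subject)
        for rnd in range(n_rounds):
            for state in states:
                state_idx = STATE_LABELS.index(state)
                rng = np.random.default_rng(
                    np.random.SeedSequence((seed, subject, rnd, state_idx))
                )
                rec_config = replace(config, schedule=ManeuverSchedule.single(state))
                trace, truth = simulate_recording(
                    rec_config, rng=rng, heart_rate=hr, amplitude_scale=amp
                )
                recordings.append(
                    CohortRecording(
                        recording_id=f"{cohort_label}-s{subject:02d}-r{rnd}-{state}",
                        subject=subject,
                        round=rnd,
                        state=state,
                        truth_class=_STATE_TRUTH[state],
                        counted=state in counted_states,
                        trace=trace,
                        ground_truth=truth,
                    )
                )
    return recordings
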