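"""Plain-text interchange formats for every pipeline stage.

Trace CSV: header ``time_s,pressure_au``, monotone time at fixed step.
Annotation JSON: list of ``{"label", "start_s", "end_s"}`` half-open
intervals.  Ground-truth, pulse-table, feature and window CSVs mirror the
in-memory containers column for column, so every stage can be re-run from
files alone.
"""
from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .classification import ClassificationResult, ThresholdModel
from .pulse_processing import Pulse
from .slope_metrics import PulseFeatures, RecordingSR, WindowSR
from .trace import Segment, SignalTrace
from .waveform_sim import GroundTruth

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_segments_json",
    "read_segments_json",
    "write_ground_truth_csv",
    "read_ground_truth_csv",
    "write_pulses_csv",
    "read_pulses_csv",
    "write_features_csv",
    "write_windows_csv",
    "write_recording_json",
    "read_recording_json",
    "write_model_json",
    "read_model_json",
    "write_results_csv",
    "read_results_csv",
]


def write_trace_csv(trace: SignalTrace, path) -> None:
    pd.DataFrame({"time_s": trace.times, "pressure_au": trace.samples}).to_csv(
        path, index=False, float_format="%.8g"
    )


def read_trace_csv(path, segments=None, sampling_rate: float | None = None) -> SignalTrace:
    """Load a trace CSV; the rate defaults to 1/median time step."""
    df = pd.read_csv(path)
    for col in ("time_s", "pressure_au"):
        if col not in df.columns:
            raise ValueError(f"trace CSV is missing column {col!r}")
    if sampling_rate is None:
        steps = np.diff(df["time_s"].to_numpy())
        if steps.size == 0 or np.median(steps) <= 0:
            raise ValueError("cannot infer sampling rate from time_s column")
        sampling_rate = 1.0 / float(np.median(steps))
    return SignalTrace(
        samples=df["pressure_au"].to_numpy(dtype=float),
        sampling_rate=sampling_rate,
        segments=list(segments) if segments else [],
    )


def write_segments_json(segments: list[Segment], path) -> None:
    with open(path, "w") as fh:
        json.dump([s.to_dict() for s in segments], fh, indent=2)
        fh.write("\n")


def read_segments_json(path) -> list[Segment]:
    with open(path) as fh:
        return [Segment.from_dict(d) for d in json.load(fh)]


def write_ground_truth_csv(truth: GroundTruth, path) -> None:
    truth.to_frame().to_csv(path, index=False, float_format="%.8g")


def read_ground_truth_csv(path) -> GroundTruth:
    df = pd.read_csv(path)
    return GroundTruth(
        foot_samples=df["foot_sample"].to_numpy(dtype=int),
        peak_samples=df["peak_sample"].to_numpy(dtype=int),
        end_samples=df["end_sample"].to_numpy(dtype=int),
        states=df["state"].to_numpy(dtype=object),
        template_sr=df["template_sr"].to_numpy(dtype=float),
    )


def write_pulses_csv(pulses: list[Pulse], path) -> None:
    pd.DataFrame(
        {
            "pulse_idx": range(len(pulses)),
            "foot_s": [p.foot_time for p in pulses],
            "peak_s": [p.peak_time for p in pulses],
            "end_s": [p.end_time for p in pulses],
            "foot_au": [p.foot_value for p in pulses],
            "peak_au": [p.peak_value for p in pulses],
            "end_au": [p.end_value for p in pulses],
            "state": [p.state if p.state is not None else "" for p in pulses],
        }
    ).to_csv(path, index=False, float_format="%.10g")


def read_pulses_csv(path, sampling_rate: float = 1000.0) -> list[Pulse]:
    """Rebuild pulses from the table; indices re-derived from times."""
    df = pd.read_csv(path, keep_default_na=False)
    pulses = []
    for _, row in df.iterrows():
        pulses.append(
            Pulse(
                foot_index=int(round(row["foot_s"] * sampling_rate)),
                peak_index=int(round(row["peak_s"] * sampling_rate)),
                end_index=int(round(row["end_s"] * sampling_rate)),
                foot_time=float(row["foot_s"]),
                peak_time=float(row["peak_s"]),
                end_time=float(row["end_s"]),
                foot_value=float(row["foot_au"]),
                peak_value=float(row["peak_au"]),
                end_value=float(row["end_au"]),
                state=str(row["state"]) or None,
            )
        )
    return pulses


def write_features_csv(
    features: list[tuple[Pulse, PulseFeatures]],
    windows: list[WindowSR],
    path,
    window_s: float = 10.0,
) -> None:
    """Per-pulse features with the index of the window holding each peak."""
    rows = []
    for i, (p, f) in enumerate(features):
        window_idx = -1
        for j, w in enumerate(windows):
            if w.start_s <= p.peak_time < w.end_s:
                window_idx = j
                break
        rows.append(
            {
                "pulse_idx": i,
                "upslope": f.upslope,
                "downslope": f.downslope,
                "sr": f.slope_ratio,
                "window_idx": window_idx,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def write_windows_csv(windows: list[WindowSR], path) -> None:
    pd.DataFrame(
        {
            "window_idx": range(len(windows)),
            "start_s": [w.start_s for w in windows],
            "end_s": [w.end_s for w in windows],
            "mean_sr": [w.mean_sr for w in windows],
            "n_pulses": [w.n_pulses for w in windows],
        }
    ).to_csv(path, index=False, float_format="%.10g")


def write_recording_json(recording: RecordingSR, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "recording_id": recording.recording_id,
                "state": recording.state,
                "sr": recording.sr,
                "n_windows": recording.n_windows,
            },
            fh,
            indent=2,
        )
        fh.write("\n")


def read_recording_json(path) -> RecordingSR:
    with open(path) as fh:
        d = json.load(fh)
    return RecordingSR(
        recording_id=d["recording_id"],
        state=d.get("state"),
        sr=float(d["sr"]),
        n_windows=int(d["n_windows"]),
    )


def write_model_json(model: ThresholdModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2)
        fh.write("\n")


def read_model_json(path) -> ThresholdModel:
    with open(path) as fh:
        return ThresholdModel.from_dict(json.load(fh))


def write_results_csv(results: list[ClassificationResult], path) -> None:
    pd.DataFrame(
        {
            "recording_id": [r.recording_id for r in results],
            "state": [r.state if r.state is not None else "" for r in results],
            "sr": [r.sr for r in results],
            "predicted": [r.predicted for r in results],
            "truth": [r.truth if r.truth is not None else "" for r in results],
        }
    ).to_csv(path, index=False, float_format="%.10g")


def read_results_csv(path) -> list[ClassificationResult]:
    df = pd.read_csv(path, keep_default_na=False)
    return [
        ClassificationResult(
            recording_id=str(row["recording_id"]),
            sr=float(row["sr"]),
            predicted=str(row["predicted"]),
            truth=str(row["truth"]) or None,
            state=str(row["state"]) or None,
        )
        for _, row in df.iterrows()
    ]
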