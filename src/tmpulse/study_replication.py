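"""End-to-end in-silico replication of the two-cohort maneuver study.

Protocol: a training cohort (3 subjects, 2 rounds) and a held-out cohort
(14 subjects, 1 round) each produce one recording per counted maneuver state
(upright baseline, 45-degree head-down tilt, hyperventilation) plus a
recovery recording used only for the maneuver-contrast statistics.  The
normal-ICP threshold is fitted as mean - 3*SD of the training cohort's
baseline recording SRs, then every counted recording in both cohorts is
classified and tallied.  Paired t-tests compare per-subject SRs for the
three contrasts (upright vs head-down, head-down vs hyperventilation,
upright vs recovery).

The held-out cohort is simulated from independent RNG streams after the
threshold is fitted, so permuting it cannot change the threshold.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

from .classification import (
    ClassificationResult,
    ConfusionMatrix,
    PairedComparison,
    ThresholdModel,
    classify,
    evaluate,
    fit_threshold,
    paired_t_test,
)
from .pulse_processing import (
    DEFAULT_BAND,
    DEFAULT_MIN_INTERVAL_S,
    DEFAULT_PROMINENCE_FRAC,
    detect_pulses,
    preprocess,
)
from .slope_metrics import (
    DEFAULT_MIN_PULSES,
    DEFAULT_WINDOW_S,
    RecordingSR,
    UnanalyzableRecording,
    extract_features,
    summarize_recording,
    window_average,
)
from .waveform_sim import (
    STATE_LABELS,
    CohortRecording,
    SimulationConfig,
    simulate_cohort,
)

__all__ = [
    "StudyDesign",
    "StudyReport",
    "process_recording",
    "run_replication",
    "render_report",
]

logger = logging.getLogger(__name__)

CONTRASTS = (
    ("upright_baseline", "head_down_tilt"),
    ("head_down_tilt", "hyperventilation"),
    ("upright_baseline", "recovery"),
)


@dataclass(frozen=True)
class StudyDesign:
    """Cohort sizes and counted states of the replication."""

    train_subjects: int = 3
    train_rounds: int = 2
    test_subjects: int = 14
    test_rounds: int = 1
    counted_states: tuple[str, ...] = (
        "upright_baseline",
        "head_down_tilt",
        "hyperventilation",
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("train_subjects", "train_rounds", "test_subjects", "test_rounds"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        unknown = set(self.counted_states) - set(STATE_LABELS)
        if unknown:
            raise ValueError(f"unknown counted states: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {
            "train_subjects": self.train_subjects,
            "train_rounds": self.train_rounds,
            "test_subjects": self.test_subjects,
            "test_rounds": self.test_rounds,
            "counted_states": list(self.counted_states),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        return cls(
            train_subjects=int(d.get("train_subjects", 3)),
            train_rounds=int(d.get("train_rounds", 2)),
            test_subjects=int(d.get("test_subjects", 14)),
            test_rounds=int(d.get("test_rounds", 1)),
            counted_states=tuple(
                d.get(
                    "counted_states",
                    ("upright_baseline", "head_down_tilt", "hyperventilation"),
                )
            ),
            seed=int(d.get("seed", 0)),
        )


def process_recording(
    rec: CohortRecording,
    band: tuple[float, float] = DEFAULT_BAND,
    min_interval: float = DEFAULT_MIN_INTERVAL_S,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    window_s: float = DEFAULT_WINDOW_S,
    min_pulses: int = DEFAULT_MIN_PULSES,
) -> RecordingSR:
    """Condition, segment and summarize one recording to its SR."""
    conditioned = preprocess(rec.trace, band=band)
    pulses = detect_pulses(conditioned, min_interval=min_interval, prominence_frac=prominence_frac)
    features, _flagged = extract_features(pulses)
    windows = window_average(
        features, window_s=window_s, min_pulses=min_pulses, segments=conditioned.segments
    )
    return summarize_recording(windows, recording_id=rec.recording_id, state=rec.state)


@dataclass
class StudyReport:
    """Everything the replication produces, serializable losslessly to JSON."""

    design: StudyDesign
    model: ThresholdModel
    calls: list[dict]  # per-recording: id, cohort, subject, round, state, sr, predicted, truth
    matrix_train: ConfusionMatrix
    matrix_test: ConfusionMatrix
    matrix_total: ConfusionMatrix
    contrasts: list[PairedComparison]
    per_subject_sr: dict[str, dict[str, float]]  # state -> {subject id -> SR}
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "design": self.design.to_dict(),
            "model": self.model.to_dict(),
            "calls": self.calls,
            "matrix_train": self.matrix_train.to_dict(),
            "matrix_test": self.matrix_test.to_dict(),
            "matrix_total": self.matrix_total.to_dict(),
            "contrasts": [c.to_dict() for c in self.contrasts],
            "per_subject_sr": self.per_subject_sr,
            "provenance": self.provenance,
        }

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "StudyReport":
        return cls(
            design=StudyDesign.from_dict(d["design"]),
            model=ThresholdModel.from_dict(d["model"]),
            calls=list(d["calls"]),
            matrix_train=ConfusionMatrix.from_dict(d["matrix_train"]),
            matrix_test=ConfusionMatrix.from_dict(d["matrix_test"]),
            matrix_total=ConfusionMatrix.from_dict(d["matrix_total"]),
            contrasts=[PairedComparison.from_dict(c) for c in d["contrasts"]],
            per_subject_sr={k: dict(v) for k, v in d["per_subject_sr"].items()},
            provenance=dict(d.get("provenance", {})),
        )

    @classmethod
    def from_json(cls, source) -> "StudyReport":
        if hasattr(source, "read"):
            return cls.from_dict(json.load(source))
        text = str(source)
        if text.lstrip().startswith("{"):
            return cls.from_dict(json.loads(text))
        with open(text) as fh:
            return cls.from_dict(json.load(fh))

    @property
    def n_correct_total(self) -> int:
        return self.matrix_total.tp + self.matrix_total.tn

    @property
    def n_correct_train(self) -> int:
        return self.matrix_train.tp + self.matrix_train.tn


def _config_hash(design: StudyDesign, config: SimulationConfig) -> str:
    payload = {
        "design": design.to_dict(),
        "sampling_rate": config.sampling_rate,
        "heart_rate_mean": config.heart_rate_mean,
        "heart_rate_subject_sd": config.heart_rate_subject_sd,
        "cycle_jitter_cv": config.cycle_jitter_cv,
        "noise_sd": config.noise_sd,
        "respiratory_drift": list(config.respiratory_drift),
        "schedule": [list(s) for s in config.schedule.segments],
        "rise_fractions": {
            label: st.morphology.mean.rise_fraction
            for label, st in config.state_params.items()
        },
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _classify_cohort(
    recordings: list[CohortRecording],
    summaries: dict[str, RecordingSR],
    model: ThresholdModel,
    cohort: str,
) -> tuple[list[ClassificationResult], list[dict]]:
    results, rows = [], []
    for rec in recordings:
        if not rec.counted:
            continue
        res = classify(summaries[rec.recording_id], model, truth=rec.truth_class)
        results.append(res)
        rows.append(
            {
                "recording_id": rec.recording_id,
                "cohort": cohort,
                "subject": rec.subject,
                "round": rec.round,
                "state": rec.state,
                "sr": res.sr,
                "predicted": res.predicted,
                "truth": rec.truth_class,
            }
        )
    return results, rows


def run_replication(
    design: StudyDesign | None = None,
    sim_config: SimulationConfig | None = None,
    *,
    band: tuple[float, float] = DEFAULT_BAND,
    window_s: float = DEFAULT_WINDOW_S,
    min_pulses: int = DEFAULT_MIN_PULSES,
    k: float = 3.0,
) -> StudyReport:
    """Run the full two-cohort replication and return its report.

    Any recording that yields no analysis window aborts the run with that
    recording's id (:class:`UnanalyzableRecording`).
    """
    if design is None:
        design = StudyDesign()
    if sim_config is None:
        sim_config = SimulationConfig(seed=design.seed)

    def summarize_all(recordings: list[CohortRecording]) -> dict[str, RecordingSR]:
        out: dict[str, RecordingSR] = {}
        for rec in recordings:
            try:
                out[rec.recording_id] = process_recording(
                    rec, band=band, window_s=window_s, min_pulses=min_pulses
                )
            except UnanalyzableRecording as exc:
                raise UnanalyzableRecording(
                    f"replication aborted: {rec.recording_id} is unanalyzable"
                ) from exc
        return out

    train = simulate_cohort(
        design.train_subjects,
        design.train_rounds,
        sim_config,
        seed=design.seed,
        counted_states=design.counted_states,
        cohort_label="train",
    )
    logger.info("simulated training cohort: %d recordings", len(train))
    train_sr = summarize_all(train)
    baseline = [
        train_sr[rec.recording_id].sr
        for rec in train
        if rec.counted and rec.state == "upright_baseline"
    ]
    model = fit_threshold(baseline, k=k)
    logger.info(
        "threshold fitted on %d baseline recordings: %.3f", model.n_train, model.threshold
    )

    test = simulate_cohort(
        design.test_subjects,
        design.test_rounds,
        sim_config,
        seed=design.seed,
        counted_states=design.counted_states,
        subject_offset=design.train_subjects,
        cohort_label="test",
    )
    logger.info("simulated held-out cohort: %d recordings", len(test))
    test_sr = summarize_all(test)

    train_results, train_rows = _classify_cohort(train, train_sr, model, "train")
    test_results, test_rows = _classify_cohort(test, test_sr, model, "test")
    matrix_train = evaluate(train_results)
    matrix_test = evaluate(test_results)
    matrix_total = ConfusionMatrix(
        tp=matrix_train.tp + matrix_test.tp,
        tn=matrix_train.tn + matrix_test.tn,
        fp=matrix_train.fp + matrix_test.fp,
        fn=matrix_train.fn + matrix_test.fn,
    )
    logger.info(
        "classified %d recordings (%d correct)",
        matrix_total.n,
        matrix_total.tp + matrix_total.tn,
    )

    # Per-subject SR by state: first-round values for training subjects,
    # the single round for held-out subjects.
    per_subject: dict[str, dict[str, float]] = {s: {} for s in STATE_LABELS}
    for recordings, summaries in ((train, train_sr), (test, test_sr)):
        for rec in recordings:
            if rec.round == 0:
                per_subject[rec.state][f"s{rec.subject:02d}"] = summaries[
                    rec.recording_id
                ].sr

    contrasts = []
    for label_a, label_b in CONTRASTS:
        subjects = sorted(set(per_subject[label_a]) & set(per_subject[label_b]))
        a = [per_subject[label_a][s] for s in subjects]
        b = [per_subject[label_b][s] for s in subjects]
        contrasts.append(paired_t_test(a, b, label_a=label_a, label_b=label_b))

    return StudyReport(
        design=design,
        model=model,
        calls=train_rows + test_rows,
        matrix_train=matrix_train,
        matrix_test=matrix_test,
        matrix_total=matrix_total,
        contrasts=contrasts,
        per_subject_sr=per_subject,
        provenance={
            "seed": design.seed,
            "config_hash": _config_hash(design, sim_config),
            "k": k,
            "band_hz": list(band),
            "window_s": window_s,
        },
    )


def _fmt_p(p: float) -> str:
    return f"{p:.2e}" if p < 1e-3 else f"{p:.3f}"


def render_report(report: StudyReport, fmt: str = "md") -> str:
    """Render the maneuver-contrast and confusion-matrix tables.

    ``fmt="md"`` gives Markdown tables; ``fmt="json"`` the full report JSON.
    A report missing a contrast or matrix is rejected with the missing name.
    """
    if fmt == "json":
        _validate_complete(report)
        return report.to_json()
    if fmt != "md":
        raise ValueError(f"unknown format {fmt!r} (expected 'md' or 'json')")
    _validate_complete(report)
    lines = []
    lines.append("## Maneuver contrasts (paired t-tests on per-subject SR)")
    lines.append("")
    lines.append("| contrast | n | t | df | p |")
    lines.append("|---|---|---|---|---|")
    for c in report.contrasts:
        lines.append(
            f"| {c.label_a} vs {c.label_b} | {c.n} | {c.t:.3f} | {c.df} | {_fmt_p(c.p)} |"
        )
    lines.append("")
    lines.append("## Classification results")
    lines.append("")
    lines.append("| cohort | n | TP | TN | FP | FN | sensitivity | specificity |")
    lines.append("|---|---|---|---|---|---|---|---|")
    for name, m in (
        ("train", report.matrix_train),
        ("test", report.matrix_test),
        ("total", report.matrix_total),
    ):
        sens = "n/a" if m.sensitivity is None else f"{m.sensitivity:.1f}%"
        spec = "n/a" if m.specificity is None else f"{m.specificity:.1f}%"
        lines.append(
            f"| {name} | {m.n} | {m.tp} | {m.tn} | {m.fp} | {m.fn} | {sens} | {spec} |"
        )
    lines.append("")
    lines.append(
        f"Threshold: {report.model.threshold:.3f} "
        f"(baseline mean {report.model.baseline_mean:.3f}, "
        f"SD {report.model.baseline_sd:.3f}, k={report.model.k:g}, "
        f"n={report.model.n_train})"
    )
    lines.append("")
    lines.append("## Per-subject SR by maneuver")
    lines.append("")
    states = [s for s in STATE_LABELS if report.per_subject_sr.get(s)]
    lines.append("| subject | " + " | ".join(states) + " |")
    lines.append("|---" * (len(states) + 1) + "|")
    subjects = sorted(
        {subj for state in states for subj in report.per_subject_sr[state]}
    )
    for subj in subjects:
        row = [subj]
        for state in states:
            v = report.per_subject_sr[state].get(subj)
            row.append("" if v is None else f"{v:.2f}")
        lines.append("| " + " | ".join(row) + " |")
    return "\n".join(lines) + "\n"


def _validate_complete(report: StudyReport) -> None:
    have = {(c.label_a, c.label_b) for c in report.contrasts}
    for contrast in CONTRASTS:
        if contrast not in have:
            raise ValueError(f"report is missing contrast {contrast[0]} vs {contrast[1]}")
    if not report.calls:
        raise ValueError("report has no classification calls")
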