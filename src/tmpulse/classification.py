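"""Threshold training, ICP-status classification and study statistics.

The decision rule is deliberately simple: the normal-ICP threshold is the
mean of the baseline (upright, resting) recording SRs minus ``k`` sample
standard deviations (default k = 3), and any recording whose SR falls
strictly below it is called *elevated* — a lower SR means a more delayed
rise, the elevated-ICP signature.  Paired t-tests compare per-subject SRs
between maneuvers, and a confusion matrix summarizes classifier accuracy.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .slope_metrics import RecordingSR

__all__ = [
    "ThresholdModel",
    "ClassificationResult",
    "ConfusionMatrix",
    "PairedComparison",
    "fit_threshold",
    "classify",
    "paired_t_test",
    "evaluate",
]


@dataclass(frozen=True)
class ThresholdModel:
    """Baseline-derived decision threshold: ``mean - k * SD`` (sample SD)."""

    baseline_mean: float
    baseline_sd: float
    k: float
    threshold: float
    n_train: int

    def to_dict(self) -> dict:
        return {
            "baseline_mean": self.baseline_mean,
            "baseline_sd": self.baseline_sd,
            "k": self.k,
            "threshold": self.threshold,
            "n_train": self.n_train,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdModel":
        return cls(
            baseline_mean=float(d["baseline_mean"]),
            baseline_sd=float(d["baseline_sd"]),
            k=float(d["k"]),
            threshold=float(d["threshold"]),
            n_train=int(d["n_train"]),
        )


def fit_threshold(baseline_srs, k: float = 3.0) -> ThresholdModel:
    """Fit the normal-ICP threshold from baseline recording SRs.

    Uses the sample (n-1) standard deviation.  Requires at least two values;
    a zero SD yields a valid but degenerate model and emits a warning.
    """
    values = np.asarray(list(baseline_srs), dtype=float)
    if values.shape[0] < 2:
        raise ValueError(
            f"need >= 2 baseline SR values to estimate an SD, got {values.shape[0]}"
        )
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        warnings.warn(
            "baseline SRs have zero spread; threshold degenerates to their mean",
            stacklevel=2,
        )
    return ThresholdModel(
        baseline_mean=mean,
        baseline_sd=sd,
        k=float(k),
        threshold=mean - k * sd,
        n_train=int(values.shape[0]),
    )


@dataclass(frozen=True)
class ClassificationResult:
    recording_id: str
    sr: float | None
    predicted: str  # "elevated" | "normal" | "unclassifiable"
    truth: str | None = None
    state: str | None = None


def classify(recording: RecordingSR, model: ThresholdModel, truth: str | None = None) -> ClassificationResult:
    """Call a recording elevated iff its SR is strictly below the threshold.

    Ties go to "normal" (the threshold is the boundary of the normal range).
    A recording without a finite SR is reported "unclassifiable" rather than
    silently normal.
    """
    sr = recording.sr
    if sr is None or not math.isfinite(sr):
        return ClassificationResult(
            recording_id=recording.recording_id,
            sr=None,
            predicted="unclassifiable",
            truth=truth,
            state=recording.state,
        )
    predicted = "elevated" if sr < model.threshold else "normal"
    return ClassificationResult(
        recording_id=recording.recording_id,
        sr=float(sr),
        predicted=predicted,
        truth=truth,
        state=recording.state,
    )


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts plus percent sensitivity/specificity (None when undefined)."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self) -> float | None:
        pos = self.tp + self.fn
        return 100.0 * self.tp / pos if pos else None

    @property
    def specificity(self) -> float | None:
        neg = self.tn + self.fp
        return 100.0 * self.tn / neg if neg else None

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConfusionMatrix":
        return cls(tp=int(d["tp"]), tn=int(d["tn"]), fp=int(d["fp"]), fn=int(d["fn"]))


def evaluate(results) -> ConfusionMatrix:
    """Tally classification results against their truth labels."""
    results = list(results)
    if not results:
        raise ValueError("cannot evaluate an empty result list")
    tp = tn = fp = fn = 0
    for r in results:
        if r.truth not in ("normal", "elevated"):
            raise ValueError(f"result {r.recording_id!r} lacks a truth label")
        if r.predicted == "unclassifiable":
            raise ValueError(f"result {r.recording_id!r} is unclassifiable")
        if r.truth == "elevated":
            if r.predicted == "elevated":
                tp += 1
            else:
                fn += 1
        else:
            if r.predicted == "normal":
                tn += 1
            else:
                fp += 1
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


@dataclass(frozen=True)
class PairedComparison:
    """Two-sided paired t-test between per-subject SRs of two conditions."""

    label_a: str
    label_b: str
    n: int
    t: float
    df: int
    p: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "label_a": self.label_a,
            "label_b": self.label_b,
            "n": self.n,
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "degenerate": self.degenerate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PairedComparison":
        return cls(
            label_a=d["label_a"],
            label_b=d["label_b"],
            n=int(d["n"]),
            t=float(d["t"]),
            df=int(d["df"]),
            p=float(d["p"]),
            degenerate=bool(d.get("degenerate", False)),
        )


def paired_t_test(a, b, label_a: str = "a", label_b: str = "b") -> PairedComparison:
    """Paired t-test: ``t = mean(d) / (SD(d) / sqrt(n))`` with d = a - b.

    Sample (n-1) SD; two-sided p from the t distribution with n-1 degrees of
    freedom.  Zero-spread differences are handled explicitly: all-zero d
    gives t = 0, p = 1; constant nonzero d is reported degenerate with an
    infinite statistic and p = 0.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"paired samples differ in length: {a.shape[0]} vs {b.shape[0]}")
    n = a.shape[0]
    if n < 2:
        raise ValueError(f"need n >= 2 pairs, got {n}")
    d = a - b
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    df = n - 1
    if sd_d == 0.0:
        if mean_d == 0.0:
            return PairedComparison(label_a, label_b, n, 0.0, df, 1.0)
        t_stat = math.inf if mean_d > 0 else -math.inf
        return PairedComparison(label_a, label_b, n, t_stat, df, 0.0, degenerate=True)
    t_stat = mean_d / (sd_d / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t_stat), df))
    return PairedComparison(label_a, label_b, n, t_stat, df, min(p, 1.0))
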