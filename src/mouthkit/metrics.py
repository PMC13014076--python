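"""Evaluation metric suite for grading classifiers and landmark detectors.

Classification: micro accuracy (correct/total), per-class recall, macro-F1.
Regression: mean absolute error and Bland-Altman limits of agreement.
Face alignment: normalized mean error (point-to-point error over
interocular distance), failure rate, cumulative error distribution.
Robustness: relative performance degradation between a baseline and a
perturbed condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "AlignmentErrorRecord",
    "DegradationReport",
    "accuracy",
    "recall",
    "macro_f1",
    "mae",
    "nme",
    "failure_rate",
    "ced_curve",
    "pr_curve",
    "bland_altman",
    "degradation",
    "DEFAULT_FAILURE_THRESHOLD",
]

#: Conventional face-alignment failure threshold on NME.
DEFAULT_FAILURE_THRESHOLD = 0.08


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class TP/FP/FN/TN tallies for a multiclass problem."""

    counts: dict  # label -> {"tp": int, "fp": int, "fn": int, "tn": int}
    total: int

    @classmethod
    def from_labels(cls, true: Sequence, pred: Sequence) -> "ConfusionCounts":
        true = list(true)
        pred = list(pred)
        if len(true) != len(pred):
            raise ValueError("true/pred length mismatch")
        if len(true) == 0:
            raise ValueError("empty label vectors")
        labels = sorted(set(true) | set(pred), key=str)
        counts = {}
        n = len(true)
        for lab in labels:
            tp = sum(1 for t, p in zip(true, pred) if t == lab and p == lab)
            fp = sum(1 for t, p in zip(true, pred) if t != lab and p == lab)
            fn = sum(1 for t, p in zip(true, pred) if t == lab and p != lab)
            counts[lab] = {"tp": tp, "fp": fp, "fn": fn, "tn": n - tp - fp - fn}
        return cls(counts=counts, total=n)

    def __post_init__(self) -> None:
        for lab, c in self.counts.items():
            if any(v < 0 for v in c.values()):
                raise ValueError(f"negative count for class {lab}")
            if sum(c.values()) != self.total:
                raise ValueError(f"class {lab} tallies do not sum to total")


@dataclass(frozen=True)
class AlignmentErrorRecord:
    """Per-face mean point-to-point error and interocular distance (px)."""

    mean_error_px: float
    interocular_px: float

    def __post_init__(self) -> None:
        if self.interocular_px <= 0:
            raise ValueError("interocular distance must be positive")
        if self.mean_error_px < 0:
            raise ValueError("error must be non-negative")

    @property
    def nme(self) -> float:
        return self.mean_error_px / self.interocular_px


@dataclass(frozen=True)
class DegradationReport:
    baseline: float
    perturbed: float
    degradation_percent: float


def accuracy(counts: ConfusionCounts) -> float:
    """Overall fraction of correctly classified items, as a percent.

    Multiclass accuracy is the micro form (sum of per-class TP over total),
    which for two classes reduces to (TP + TN) / (TP + TN + FP + FN).
    """
    if counts.total == 0:
        raise ValueError("cannot compute accuracy of zero items")
    correct = sum(c["tp"] for c in counts.counts.values())
    return 100.0 * correct / counts.total


def recall(counts: ConfusionCounts, class_label) -> float:
    """TP / (TP + FN) for one class, as a percent."""
    c = counts.counts[class_label]
    denom = c["tp"] + c["fn"]
    if denom == 0:
        raise ValueError(f"recall undefined: no true items of class {class_label}")
    return 100.0 * c["tp"] / denom


def macro_f1(counts: ConfusionCounts) -> float:
    """Unweighted mean of per-class F1 scores, in [0, 1].

    A class with precision + recall = 0 contributes F1 = 0 (standard
    convention, warned); classes absent from both truth and predictions
    are excluded with a warning.
    """
    f1s = []
    for lab, c in counts.counts.items():
        if c["tp"] + c["fp"] + c["fn"] == 0:
            warnings.warn(f"class {lab} has no items; excluded from macro-F1")
            continue
        prec = c["tp"] / (c["tp"] + c["fp"]) if c["tp"] + c["fp"] > 0 else 0.0
        rec = c["tp"] / (c["tp"] + c["fn"]) if c["tp"] + c["fn"] > 0 else 0.0
        if prec + rec == 0:
            warnings.warn(f"class {lab}: precision + recall = 0, F1 set to 0")
            f1s.append(0.0)
        else:
            f1s.append(2 * prec * rec / (prec + rec))
    if not f1s:
        raise ValueError("no scoreable class for macro-F1")
    return float(np.mean(f1s))


def mae(pred: Sequence[float], truth: Sequence[float]) -> float:
    """Mean absolute error, in the units of the inputs."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.ndim != 1 or p.size == 0:
        raise ValueError("pred and truth must be equal-length non-empty 1D arrays")
    return float(np.mean(np.abs(p - t)))


def _nmes(records: Sequence[AlignmentErrorRecord]) -> np.ndarray:
    if len(records) == 0:
        raise ValueError("no alignment records")
    return np.array([r.nme for r in records])


def nme(records: Sequence[AlignmentErrorRecord]) -> float:
    """Mean normalized error: mean over faces of error / interocular distance."""
    return float(np.mean(_nmes(records)))


def failure_rate(records: Sequence[AlignmentErrorRecord], threshold: float = DEFAULT_FAILURE_THRESHOLD) -> float:
    """Percent of faces with NME strictly above the threshold."""
    vals = _nmes(records)
    return 100.0 * float(np.mean(vals > threshold))


def ced_curve(records: Sequence[AlignmentErrorRecord], thresholds: Sequence[float]) -> np.ndarray:
    """Cumulative error distribution: fraction of faces with NME <= t."""
    vals = _nmes(records)
    ts = np.asarray(thresholds, dtype=float)
    return np.array([float(np.mean(vals <= t)) for t in ts])


def pr_curve(scores: Sequence[float], labels: Sequence[int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precision and recall at every distinct score threshold.

    Items with ``score >= threshold`` are predicted positive; thresholds
    are the distinct scores in descending order. Returns
    (precision, recall, thresholds).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1 or s.size == 0:
        raise ValueError("scores and labels must be equal-length non-empty 1D arrays")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == y.size:
        raise ValueError("need at least one positive and one negative label")
    thresholds = np.unique(s)[::-1]
    precisions, recalls = [], []
    for t in thresholds:
        predicted = s >= t
        tp = int(np.sum(predicted & (y == 1)))
        fp = int(np.sum(predicted & (y == 0)))
        precisions.append(tp / (tp + fp))
        recalls.append(tp / n_pos)
    return np.array(precisions), np.array(recalls), thresholds


def bland_altman(pred: Sequence[float], truth: Sequence[float]) -> tuple[float, float, float]:
    """Bland-Altman agreement: (mean difference, lower LoA, upper LoA).

    Limits of agreement are mean +/- 1.96 * SD of the paired differences
    (sample SD). Differences are pred - truth.
    """
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.ndim != 1 or p.size < 2:
        raise ValueError("pred and truth must be equal-length 1D arrays with >= 2 items")
    d = p - t
    md = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return md, md - 1.96 * sd, md + 1.96 * sd


def degradation(baseline: float, perturbed: float) -> DegradationReport:
    """Relative performance drop, percent, for a higher-is-better metric.

    ``100 * (baseline - perturbed) / baseline``; negative when the
    perturbed condition improves on the baseline.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    pct = 100.0 * (baseline - perturbed) / baseline
    return DegradationReport(baseline=baseline, perturbed=perturbed, degradation_percent=pct)
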