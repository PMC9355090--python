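"""Three-class confusion-matrix evaluation.

Matrix orientation: rows are the forecast (predicted) class, columns the
true class, over the fixed label order (healthy, unhealthy, none). From the
matrix each class's TP/FP/FN/TN are derived and summarised as

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 · precision · recall / (precision + recall)

with overall accuracy = trace / total. Zero denominators yield 0 with an
``undefined`` flag rather than an error, so batch reports never abort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LABELS",
    "ClassCounts",
    "ClassMetrics",
    "confusion",
    "per_class_counts",
    "metrics",
    "accuracy",
    "misclassified",
    "format_percent",
    "report",
]

#: Fixed class order used everywhere (row/column order, network head order).
LABELS: tuple[str, str, str] = ("healthy", "unhealthy", "none")
_INDEX = {name: i for i, name in enumerate(LABELS)}


@dataclass(frozen=True)
class ClassCounts:
    """One-vs-rest tallies for a single class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    undefined: bool = False


def _label_index(label: str) -> int:
    try:
        return _INDEX[label]
    except KeyError:
        raise ValueError(f"unknown label {label!r}; expected one of {LABELS}") from None


def confusion(true_labels, predicted_labels) -> np.ndarray:
    """3×3 count matrix: ``cm[p, t]`` = samples predicted p with truth t."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must have equal length")
    cm = np.zeros((3, 3), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        cm[_label_index(p), _label_index(t)] += 1
    return cm


def _validate_cm(cm: np.ndarray) -> np.ndarray:
    cm = np.asarray(cm)
    if cm.shape != (3, 3):
        raise ValueError(f"expected a 3×3 matrix, got {cm.shape}")
    if (cm < 0).any():
        raise ValueError("confusion matrix entries must be nonnegative")
    return cm


def per_class_counts(cm: np.ndarray, label: str) -> ClassCounts:
    """TP/FP/FN/TN for one class from the predicted×true matrix."""
    cm = _validate_cm(cm)
    c = _label_index(label)
    tp = int(cm[c, c])
    fp = int(cm[c, :].sum() - tp)  # predicted c, truth elsewhere
    fn = int(cm[:, c].sum() - tp)  # truth c, predicted elsewhere
    tn = int(cm.sum() - tp - fp - fn)
    return ClassCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics(counts: ClassCounts) -> ClassMetrics:
    """Precision/recall/F1 with the zero-denominator → 0 convention."""
    undefined = False
    if counts.tp + counts.fp == 0:
        precision, undefined = 0.0, True
    else:
        precision = counts.tp / (counts.tp + counts.fp)
    if counts.tp + counts.fn == 0:
        recall, undefined = 0.0, True
    else:
        recall = counts.tp / (counts.tp + counts.fn)
    if precision + recall == 0:
        f1 = 0.0
        if undefined:
            warnings.warn("metrics undefined: no predicted and no true samples", stacklevel=2)
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return ClassMetrics(precision=precision, recall=recall, f1=f1, undefined=undefined)


def accuracy(cm: np.ndarray) -> float:
    """trace / total."""
    cm = _validate_cm(cm)
    total = int(cm.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm)) / total


def misclassified(cm: np.ndarray) -> int:
    """Number of off-diagonal samples."""
    cm = _validate_cm(cm)
    return int(cm.sum() - np.trace(cm))


def format_percent(fraction: float) -> str:
    """Render a fraction as a percentage, two decimals rounded
    half-away-from-zero, trailing zeros (and a bare point) trimmed:
    0.92 → "92%", 0.9756 → "97.56%"."""
    pct = fraction * 100.0
    scaled = np.floor(abs(pct) * 100.0 + 0.5) / 100.0
    text = f"{scaled:.2f}".rstrip("0").rstrip(".")
    sign = "-" if pct < 0 else ""
    return f"{sign}{text}%"


def report(true_labels, predicted_labels) -> dict:
    """Full evaluation report as a JSON-serialisable dict."""
    cm = confusion(true_labels, predicted_labels)
    per_class = {}
    for label in LABELS:
        counts = per_class_counts(cm, label)
        m = metrics(counts)
        per_class[label] = {
            "tp": counts.tp,
            "fp": counts.fp,
            "fn": counts.fn,
            "tn": counts.tn,
            "precision": m.precision,
            "recall": m.recall,
            "f1": m.f1,
            "precision_pct": format_percent(m.precision),
            "recall_pct": format_percent(m.recall),
            "f1_pct": format_percent(m.f1),
        }
    return {
        "labels": list(LABELS),
        "confusion_matrix": cm.tolist(),
        "per_class": per_class,
        "accuracy": accuracy(cm),
        "accuracy_pct": format_percent(accuracy(cm)),
        "misclassified": misclassified(cm),
        "total": int(cm.sum()),
    }
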