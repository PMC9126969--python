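"""Classification metrics: confusion matrix, macro precision/recall/F1, top-k.

Per-class counts follow the one-vs-rest convention: for class ``c``,
TP = cm[c, c], FP = (column c) - TP, FN = (row c) - TP, TN = rest.
Accuracy is the global trace/total; precision, recall and F1 are
macro-averaged (unweighted mean over classes).  A class whose denominator
is empty (no predicted or no true samples) contributes 0 to the macro
average — the conservative convention — and the event is logged.

Top-k accuracy is the fraction of samples whose true label appears among
the k largest predicted probabilities, ties broken deterministically in
favour of the lower class index.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """Square count matrix, rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError(f"confusion matrix must be square, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix counts must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path, class_names: list[str] | None = None) -> None:
        import pandas as pd

        names = class_names or [str(i) for i in range(self.n_classes)]
        pd.DataFrame(self.counts, index=names, columns=names).to_csv(path)


@dataclass
class EvalReport:
    """Aggregate metrics over one evaluation set, all fractions in [0, 1]."""

    accuracy: float
    precision_macro: float
    recall_macro: float
    f1_macro: float
    top1: float | None = None
    top5: float | None = None
    confusion: ConfusionMatrix | None = None
    model_name: str | None = None
    per_class: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "model_name": self.model_name,
            "accuracy": self.accuracy,
            "precision_macro": self.precision_macro,
            "recall_macro": self.recall_macro,
            "f1_macro": self.f1_macro,
            "top1": self.top1,
            "top5": self.top5,
        }
        if self.confusion is not None:
            d["confusion"] = self.confusion.counts.tolist()
        if self.per_class:
            d["per_class"] = {k: list(map(float, v)) for k, v in self.per_class.items()}
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def to_csv(self, path) -> None:
        """One-row CSV of the headline metrics."""
        import csv

        fields = ["model_name", "accuracy", "precision_macro",
                  "recall_macro", "f1_macro", "top1", "top5"]
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(fields)
            writer.writerow([getattr(self, f) for f in fields])


def confusion_matrix(y_true, y_pred, n_classes: int) -> ConfusionMatrix:
    """Count matrix with counts[i, j] = #(true == i and predicted == j)."""
    y_true = np.asarray(y_true, dtype=np.int64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.int64).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("true and predicted label arrays differ in length")
    for name, arr in (("true", y_true), ("predicted", y_pred)):
        bad = np.flatnonzero((arr < 0) | (arr >= n_classes))
        if bad.size:
            raise ValueError(
                f"{name} label out of range [0, {n_classes}) at index {bad[0]}: {arr[bad[0]]}"
            )
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return ConfusionMatrix(cm)


def per_class_counts(cm: ConfusionMatrix, c: int) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, FP, FN, TN) for class ``c``."""
    counts = cm.counts
    tp = int(counts[c, c])
    fp = int(counts[:, c].sum()) - tp
    fn = int(counts[c, :].sum()) - tp
    tn = cm.total - tp - fp - fn
    return tp, fp, fn, tn


def metrics(cm: ConfusionMatrix) -> EvalReport:
    """Accuracy plus macro-averaged precision/recall/F1 from a confusion matrix."""
    total = cm.total
    if total == 0:
        raise ValueError("cannot compute metrics on an empty confusion matrix")
    accuracy = float(np.trace(cm.counts)) / total
    precisions, recalls, f1s = [], [], []
    for c in range(cm.n_classes):
        tp, fp, fn, _ = per_class_counts(cm, c)
        if tp + fp == 0:
            logger.debug("class %d has no predicted samples; precision scored 0", c)
            p = 0.0
        else:
            p = tp / (tp + fp)
        if tp + fn == 0:
            logger.debug("class %d has no true samples; recall scored 0", c)
            r = 0.0
        else:
            r = tp / (tp + fn)
        f = 0.0 if p + r == 0 else 2 * p * r / (p + r)
        precisions.append(p)
        recalls.append(r)
        f1s.append(f)
    return EvalReport(
        accuracy=accuracy,
        precision_macro=float(np.mean(precisions)),
        recall_macro=float(np.mean(recalls)),
        f1_macro=float(np.mean(f1s)),
        confusion=cm,
        per_class={"precision": precisions, "recall": recalls, "f1": f1s},
    )


def top_k_accuracy(probabilities, y_true, k: int) -> float:
    """Fraction of rows whose true label is among the k most probable classes.

    Ties are resolved in favour of the lower class index: with equal
    probabilities the lower-indexed class is ranked higher, making the
    result deterministic.
    """
    proba = np.asarray(probabilities, dtype=np.float64)
    y_true = np.asarray(y_true, dtype=np.int64).ravel()
    if proba.ndim != 2 or proba.shape[0] != y_true.shape[0]:
        raise ValueError("probability matrix rows must match label count")
    n_classes = proba.shape[1]
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > n_classes:
        raise ValueError(f"k={k} exceeds the number of classes {n_classes}")
    if y_true.size == 0:
        return 0.0
    # stable rank: sort descending by probability, ascending by index on ties
    order = np.argsort(-proba, axis=1, kind="stable")
    topk = order[:, :k]
    hits = (topk == y_true[:, None]).any(axis=1)
    return float(hits.mean())


def evaluate_predictions(probabilities, y_true, n_classes: int,
                         model_name: str | None = None) -> EvalReport:
    """Full report (confusion, macro metrics, top-1 and top-5) from probabilities."""
    proba = np.asarray(probabilities, dtype=np.float64)
    y_pred = np.argmax(proba, axis=1)
    cm = confusion_matrix(y_true, y_pred, n_classes)
    report = metrics(cm)
    report.top1 = top_k_accuracy(proba, y_true, 1)
    report.top5 = top_k_accuracy(proba, y_true, min(5, n_classes))
    report.model_name = model_name
    return report
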