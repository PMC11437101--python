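"""Confusion-matrix diagnostics for the federated classifier.

All metrics derive from the four confusion counts. For multiclass tasks the
default reduction is micro-averaged one-vs-rest: per-class counts are summed
before any ratio is taken, so every (sample, class) pair contributes once.
Zero-denominator cells raise :class:`UndefinedMetricError` instead of
silently reporting 0 — silent zeros corrupt aggregate tables.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "UndefinedMetricError",
    "confusion_from_predictions",
    "tpr",
    "fpr",
    "precision",
    "recall",
    "accuracy",
    "f_measure",
    "evaluate_run",
    "write_report",
]


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero; the cell has no defined value."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.total < 1:
            raise ValueError("confusion counts must total at least 1")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_from_predictions(y_true, y_pred, positive_class=None) -> ConfusionCounts:
    """Confusion counts from label arrays.

    With `positive_class` given, a binary one-vs-rest tally. Without it,
    micro mode: one-vs-rest counts summed over every class present in
    y_true or y_pred (so the counts total C*n for C classes).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    if y_true.size == 0:
        raise ValueError("empty prediction arrays")
    if positive_class is not None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
        if positive_class not in classes:
            raise ValueError(f"unknown positive_class {positive_class!r}")
        t = y_true == positive_class
        p = y_pred == positive_class
        return ConfusionCounts(
            tp=int(np.sum(t & p)),
            tn=int(np.sum(~t & ~p)),
            fp=int(np.sum(~t & p)),
            fn=int(np.sum(t & ~p)),
        )
    tp = tn = fp = fn = 0
    for c in np.unique(np.concatenate([y_true, y_pred])):
        cc = confusion_from_predictions(y_true, y_pred, positive_class=c)
        tp += cc.tp; tn += cc.tn; fp += cc.fp; fn += cc.fn
    return ConfusionCounts(tp, tn, fp, fn)


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        raise UndefinedMetricError(f"{name} undefined: zero denominator")
    return num / den


def tpr(c: ConfusionCounts) -> float:
    """True-positive rate TP/(TP+FN); identical to recall."""
    return _ratio(c.tp, c.tp + c.fn, "TPR")


def fpr(c: ConfusionCounts) -> float:
    """False-positive rate FP/(FP+TN)."""
    return _ratio(c.fp, c.fp + c.tn, "FPR")


def precision(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fp, "precision")


def recall(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fn, "recall")


def accuracy(c: ConfusionCounts) -> float:
    return _ratio(c.tp + c.tn, c.total, "accuracy")


def f_measure(precision_value: float, recall_value: float) -> float:
    """Harmonic mean 2PR/(P+R); inputs and output share one scale
    (fractions in, fraction out; percents in, percent out)."""
    if precision_value + recall_value <= 0:
        raise UndefinedMetricError("F-measure undefined: P + R is zero")
    return 2 * precision_value * recall_value / (precision_value + recall_value)


@dataclass
class MetricsReport:
    """Full metric block for one evaluation, all on the [0, 1] scale."""

    counts: ConfusionCounts
    accuracy: float
    precision: float
    recall: float
    fpr: float
    f_measure: float
    per_class: dict | None = None

    @classmethod
    def from_counts(cls, counts: ConfusionCounts,
                    per_class: dict | None = None) -> "MetricsReport":
        p = precision(counts)
        r = recall(counts)
        return cls(
            counts=counts,
            accuracy=accuracy(counts),
            precision=p,
            recall=r,
            fpr=fpr(counts),
            f_measure=f_measure(p, r),
            per_class=per_class,
        )

    def to_dict(self) -> dict:
        d = {
            "TP": self.counts.tp, "TN": self.counts.tn,
            "FP": self.counts.fp, "FN": self.counts.fn,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "fpr": self.fpr,
            "f_measure": self.f_measure,
        }
        if self.per_class is not None:
            d["per_class"] = self.per_class
        return d


def evaluate_run(model, X_test: np.ndarray, y_test: np.ndarray,
                 mode: str = "micro") -> MetricsReport:
    """Predict on held-out data and derive the full metric block.

    mode "micro" (default) sums one-vs-rest counts over classes; the
    per-class tables are attached either way. Undefined per-class cells are
    reported as None, leaving the rest of the table filled.
    """
    from .rdbn_model import predict  # local import avoids a cycle

    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    y_test = np.asarray(y_test, dtype=int)
    if X_test.shape[0] == 0:
        raise ValueError("empty test set")
    if mode != "micro":
        raise ValueError(f"unknown evaluation mode {mode!r}")
    y_pred = predict(model, X_test)
    per_class: dict = {}
    for c in np.unique(np.concatenate([y_test, y_pred])):
        cc = confusion_from_predictions(y_test, y_pred, positive_class=c)
        row = {"TP": cc.tp, "TN": cc.tn, "FP": cc.fp, "FN": cc.fn}
        for name, fn in (("precision", precision), ("recall", recall),
                         ("fpr", fpr), ("accuracy", accuracy)):
            try:
                row[name] = fn(cc)
            except UndefinedMetricError:
                row[name] = None
        per_class[int(c)] = row
    counts = confusion_from_predictions(y_test, y_pred)
    return MetricsReport.from_counts(counts, per_class=per_class)


def write_report(report: MetricsReport, json_path=None, csv_path=None,
                 dataset: str = "synthetic") -> None:
    """Persist a report as JSON and/or a one-row CSV table."""
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump({"dataset": dataset, **report.to_dict()}, fh, indent=2)
    if csv_path is not None:
        cols = ["dataset", "TP", "TN", "FP", "FN", "accuracy", "precision",
                "recall", "fpr", "f_measure"]
        row = {"dataset": dataset, **{k: v for k, v in report.to_dict().items()
                                      if k != "per_class"}}
        with open(csv_path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=cols)
            w.writeheader()
            w.writerow(row)
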