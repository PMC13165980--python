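"""Confusion matrices and the seven diagnostic metrics.

All metrics are percentages in [0, 100], computed from one-vs-rest
TP/TN/FP/FN counts of a K x K confusion matrix (rows = true class,
columns = predicted class):

    accuracy          = 100 * (TP+TN) / (TP+TN+FP+FN)
    precision         = 100 * TP / (TP+FP)
    recall            = 100 * TP / (TP+FN)        (sensitivity)
    f1                = 2 * precision * recall / (precision + recall)
    specificity       = 100 * TN / (TN+FP)        (true negative rate)
    balanced_accuracy = (recall + specificity) / 2
    g_mean            = sqrt(recall * specificity)

Macro values are unweighted means over classes.  All arithmetic is done
on unrounded ratios; rounding is applied only for display (half away
from zero, default 2 decimals).  Zero-denominator ratios are defined as
0 with a warning — conservative under recall-driven selection.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "MetricsError",
    "confusion_from_predictions",
    "accuracy",
    "precision",
    "recall",
    "specificity",
    "f1",
    "balanced_accuracy",
    "g_mean",
    "report",
    "round_display",
]

METRIC_NAMES = (
    "accuracy",
    "precision",
    "recall",
    "f1",
    "specificity",
    "balanced_accuracy",
    "g_mean",
)

#: Column order used by rendered report tables.
DISPLAY_ORDER = (
    "accuracy",
    "precision",
    "recall",
    "f1",
    "specificity",
    "balanced_accuracy",
    "g_mean",
)


class MetricsError(ValueError):
    """Raised for malformed confusion matrices or metric inputs."""


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, defining value as 0", stacklevel=3)
        return 0.0
    return 100.0 * num / den


def accuracy(tp: float, tn: float, fp: float, fn: float) -> float:
    """Percent of all predictions that are correct."""
    return _ratio(tp + tn, tp + tn + fp + fn, "accuracy")


def precision(tp: float, fp: float) -> float:
    """Percent of positive predictions that are truly positive."""
    return _ratio(tp, tp + fp, "precision")


def recall(tp: float, fn: float) -> float:
    """Percent of actual positives that are identified (sensitivity)."""
    return _ratio(tp, tp + fn, "recall")


def specificity(tn: float, fp: float) -> float:
    """Percent of actual negatives that are identified (true negative rate)."""
    return _ratio(tn, tn + fp, "specificity")


def f1(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of precision and recall, both given as percentages."""
    if precision_pct == 0 and recall_pct == 0:
        return 0.0
    return 2.0 * precision_pct * recall_pct / (precision_pct + recall_pct)


def balanced_accuracy(recall_pct: float, specificity_pct: float) -> float:
    """Arithmetic mean of recall and specificity."""
    return (recall_pct + specificity_pct) / 2.0


def g_mean(recall_pct: float, specificity_pct: float) -> float:
    """Geometric mean of recall and specificity."""
    return math.sqrt(recall_pct * specificity_pct)


def round_display(value: float, decimals: int = 2) -> float:
    """Round half away from zero at the given number of decimals."""
    factor = 10**decimals
    return math.copysign(math.floor(abs(value) * factor + 0.5), value) / factor


@dataclass
class ConfusionMatrix:
    """K x K integer counts; rows are true classes, columns predictions."""

    class_order: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.class_order)
        if k < 2:
            raise MetricsError("confusion matrix needs at least 2 classes")
        if self.counts.shape != (k, k):
            raise MetricsError(
                f"counts shape {self.counts.shape} does not match {k} classes"
            )
        if (self.counts < 0).any():
            raise MetricsError("confusion counts must be nonnegative")

    def one_vs_rest(self, code: str) -> tuple:
        """(TP, TN, FP, FN) for one class against all others."""
        i = self.class_order.index(code)
        tp = self.counts[i, i]
        fp = self.counts[:, i].sum() - tp
        fn = self.counts[i, :].sum() - tp
        tn = self.counts.sum() - tp - fp - fn
        return int(tp), int(tn), int(fp), int(fn)

    def collapse(self, mapping: Mapping[str, str], group_order: Sequence[str]) -> "ConfusionMatrix":
        """Merge classes into groups (e.g. six lesion classes -> benign/malignant)."""
        k = len(group_order)
        out = np.zeros((k, k), dtype=self.counts.dtype)
        gi = {g: i for i, g in enumerate(group_order)}
        for i, ci in enumerate(self.class_order):
            for j, cj in enumerate(self.class_order):
                out[gi[mapping[ci]], gi[mapping[cj]]] += self.counts[i, j]
        return ConfusionMatrix(list(group_order), out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_order, columns=self.class_order)


def confusion_from_predictions(
    true_labels: Sequence[str], predicted_labels: Sequence[str], class_order: Sequence[str]
) -> ConfusionMatrix:
    """Tabulate counts[i][j] = #{true == class_order[i], predicted == class_order[j]}."""
    if len(true_labels) != len(predicted_labels):
        raise MetricsError("true and predicted label lists differ in length")
    index = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise MetricsError(f"label outside class_order: {t!r}/{p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(list(class_order), counts)


@dataclass
class MetricReport:
    """Per-class and macro-averaged values of the seven metrics (percent)."""

    per_class: dict  # code -> {metric: value}
    macro: dict  # metric -> value
    rounding: int = 2
    positive_class: str | None = None

    def display(self) -> pd.DataFrame:
        """Rounded table, one row per class plus a macro row."""
        rows = {c: {m: round_display(v, self.rounding) for m, v in vals.items()}
                for c, vals in self.per_class.items()}
        rows["macro"] = {m: round_display(v, self.rounding) for m, v in self.macro.items()}
        return pd.DataFrame(rows).T[list(DISPLAY_ORDER)]

    def to_json(self) -> str:
        return json.dumps({"per_class": self.per_class, "macro": self.macro})

    def to_csv(self, path) -> None:
        self.display().to_csv(path, index_label="class")

    # -- selection support -------------------------------------------------
    def key_metrics(self) -> dict:
        """The four metrics of the selection cascade for this report.

        Binary reports expose the positive class's values (table-row
        semantics: the first named class of a task is the positive
        class); multi-class reports expose macro values.
        """
        src = (
            self.per_class[self.positive_class]
            if self.positive_class is not None
            else self.macro
        )
        return {m: src[m] for m in ("recall", "f1", "precision", "accuracy")}

    @classmethod
    def from_binary_row(
        cls,
        positive_class: str,
        *,
        accuracy: float,
        precision: float,
        recall: float,
        f1: float,
        specificity: float | None = None,
        balanced_accuracy: float | None = None,
        g_mean: float | None = None,
    ) -> "MetricReport":
        """Build a report from published single-row binary results.

        Used for worked examples where only the positive-class row of a
        binary evaluation is available (reference benchmark tables).
        """
        row = {
            "accuracy": accuracy,
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "specificity": float("nan") if specificity is None else specificity,
            "balanced_accuracy": float("nan") if balanced_accuracy is None else balanced_accuracy,
            "g_mean": float("nan") if g_mean is None else g_mean,
        }
        return cls(per_class={positive_class: row}, macro=dict(row),
                   positive_class=positive_class)


def report(conf: ConfusionMatrix, positive_class: str | None = None) -> MetricReport:
    """Per-class one-vs-rest metrics and their unweighted macro average.

    ``positive_class`` marks which class a binary task treats as positive
    (defaults to the first class for K=2); it only affects which row
    :meth:`MetricReport.key_metrics` reads, never the values.
    """
    if conf.counts.sum() == 0:
        raise MetricsError("empty confusion matrix")
    per_class: dict = {}
    for code in conf.class_order:
        tp, tn, fp, fn = conf.one_vs_rest(code)
        if tp + fn == 0:
            warnings.warn(f"class {code!r} has no true instances", stacklevel=2)
        p = precision(tp, fp)
        r = recall(tp, fn)
        s = specificity(tn, fp)
        per_class[code] = {
            "accuracy": accuracy(tp, tn, fp, fn),
            "precision": p,
            "recall": r,
            "f1": f1(p, r),
            "specificity": s,
            "balanced_accuracy": balanced_accuracy(r, s),
            "g_mean": g_mean(r, s),
        }
    macro = {
        m: float(np.mean([vals[m] for vals in per_class.values()])) for m in METRIC_NAMES
    }
    if positive_class is None and len(conf.class_order) == 2:
        positive_class = conf.class_order[0]
    return MetricReport(per_class=per_class, macro=macro, positive_class=positive_class)
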