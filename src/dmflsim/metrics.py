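"""Confusion-matrix construction and one-vs-rest performance measures.

For a K-class problem the confusion matrix C has rows = true class and
columns = predicted class.  Each class k is reduced one-vs-rest to binary
counts (TP, TN, FP, FN) from which the standard measures follow:

    ACC = (TP + TN) / (TP + TN + FP + FN)
    PRE = TP / (TP + FP)
    REC = TP / (TP + FN)
    SPF = TN / (TN + FP)
    F1  = 2 * PRE * REC / (PRE + REC)

Macro averaging (the default) is the unweighted mean over classes.  Because
the one-vs-rest ACC and the plain overall accuracy (trace / total) are both
defensible readings in the multiclass case, the report carries both, clearly
labeled.  A per-class ratio with a zero denominator yields 0 with a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "BinaryCounts",
    "MetricReport",
    "confusion_matrix",
    "one_vs_rest_counts",
    "compute_metrics",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (c < 0).any():
            raise ValueError("confusion-matrix entries must be nonnegative")
        if len(self.class_names) != c.shape[0]:
            raise ValueError("class_names length must match matrix size")
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "class_names", tuple(self.class_names))

    @property
    def num_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.counts, index=list(self.class_names), columns=list(self.class_names)).to_csv(path)


@dataclass(frozen=True)
class BinaryCounts:
    """One-vs-rest reduction of a confusion matrix for one designated class."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricReport:
    """Macro-averaged (or per-class) performance measures, all in [0, 1].

    ``accuracy`` is the plain overall accuracy trace/total;
    ``accuracy_ovr_macro`` is the macro mean of the one-vs-rest binary
    accuracies — the two coincide only for K = 2.
    """

    accuracy: float
    accuracy_ovr_macro: float
    precision: float
    recall: float
    specificity: float
    f1: float
    averaging: str = "macro"
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "accuracy_ovr_macro": self.accuracy_ovr_macro,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
            "averaging": self.averaging,
            "per_class": self.per_class,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def confusion_matrix(
    true_labels: Sequence[int],
    predicted_labels: Sequence[int],
    num_classes: int,
    class_names: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Count table: ``counts[t][p]`` = number of samples with true class t
    predicted as p."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.size == 0:
        raise ValueError("label sequences must be nonempty")
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.size} true vs {p.size} predicted labels")
    if (t < 0).any() or (t >= num_classes).any() or (p < 0).any() or (p >= num_classes).any():
        raise ValueError(f"labels must lie in [0, {num_classes})")
    counts = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    if class_names is None:
        class_names = [f"class{k}" for k in range(num_classes)]
    return ConfusionMatrix(counts, tuple(class_names))


def one_vs_rest_counts(cm: ConfusionMatrix, class_k: int) -> BinaryCounts:
    """Binary TP/TN/FP/FN for ``class_k`` against all other classes."""
    if not 0 <= class_k < cm.num_classes:
        raise ValueError(f"class index {class_k} out of range")
    c = cm.counts
    tp = int(c[class_k, class_k])
    fn = int(c[class_k].sum()) - tp
    fp = int(c[:, class_k].sum()) - tp
    tn = cm.total - tp - fn - fp
    return BinaryCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def _ratio(num: float, den: float, what: str, cls: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined for class {cls!r} (zero denominator); reporting 0")
        return 0.0
    return num / den


def compute_metrics(cm: ConfusionMatrix, averaging: str = "macro") -> MetricReport:
    """Per-class one-vs-rest measures and their macro average."""
    if averaging not in ("macro", "per_class"):
        raise ValueError("averaging must be 'macro' or 'per_class'")
    if cm.total == 0:
        raise ValueError("cannot compute metrics from an empty confusion matrix")
    per_class: dict[str, dict[str, float]] = {}
    accs, pres, recs, spfs, f1s = [], [], [], [], []
    for k, name in enumerate(cm.class_names):
        b = one_vs_rest_counts(cm, k)
        acc = (b.TP + b.TN) / b.total
        pre = _ratio(b.TP, b.TP + b.FP, "precision", name)
        rec = _ratio(b.TP, b.TP + b.FN, "recall", name)
        spf = _ratio(b.TN, b.TN + b.FP, "specificity", name)
        f1 = _ratio(2.0 * pre * rec, pre + rec, "F1", name)
        per_class[name] = {
            "accuracy": acc, "precision": pre, "recall": rec, "specificity": spf, "f1": f1,
        }
        accs.append(acc); pres.append(pre); recs.append(rec); spfs.append(spf); f1s.append(f1)
    return MetricReport(
        accuracy=float(np.trace(cm.counts)) / cm.total,
        accuracy_ovr_macro=float(np.mean(accs)),
        precision=float(np.mean(pres)),
        recall=float(np.mean(recs)),
        specificity=float(np.mean(spfs)),
        f1=float(np.mean(f1s)),
        averaging=averaging,
        per_class=per_class,
    )
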