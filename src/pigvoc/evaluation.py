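"""Confusion matrices and multi-class evaluation metrics.

Per class c (one-vs-rest): TP = confusion[c, c]; FN = row c minus TP;
FP = column c minus TP; TN = everything else.  Reported metrics:

    recall      = TP / (TP + FN)
    specificity = 1 - FP / (FP + TN)
    accuracy    = trace / total  (single multi-class number)

Macro values are unweighted means over classes; classes whose denominator
is zero are reported as NaN and excluded from the macro mean (flagged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EvalReport", "confusion_matrix", "metrics"]


@dataclass
class EvalReport:
    confusion: np.ndarray
    class_order: list[str]
    recall: np.ndarray  # per class; NaN where undefined
    specificity: np.ndarray
    accuracy: float
    macro_recall: float
    macro_specificity: float
    undefined_classes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "class_order": list(self.class_order),
            "confusion": self.confusion.tolist(),
            "recall": self.recall.tolist(),
            "specificity": self.specificity.tolist(),
            "accuracy": self.accuracy,
            "macro_recall": self.macro_recall,
            "macro_specificity": self.macro_specificity,
            "undefined_classes": list(self.undefined_classes),
        }


def confusion_matrix(true_labels, predicted_labels, class_order) -> np.ndarray:
    """K x K count matrix; rows = true class, columns = predicted class."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must have equal length")
    index = {lab: i for i, lab in enumerate(class_order)}
    mat = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index:
            raise ValueError(f"unknown true label {t!r}")
        if p not in index:
            raise ValueError(f"unknown predicted label {p!r}")
        mat[index[t], index[p]] += 1
    return mat


def metrics(confusion: np.ndarray, class_order=None) -> EvalReport:
    """Per-class recall/specificity and overall accuracy from a confusion
    matrix."""
    confusion = np.asarray(confusion)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1]:
        raise ValueError("confusion matrix must be square")
    K = confusion.shape[0]
    if K < 2:
        raise ValueError("need at least 2 classes")
    total = int(confusion.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    if class_order is None:
        class_order = [str(i) for i in range(K)]
    tp = np.diag(confusion).astype(float)
    fn = confusion.sum(axis=1) - tp
    fp = confusion.sum(axis=0) - tp
    tn = total - tp - fn - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        specificity = np.where(fp + tn > 0, 1.0 - fp / (fp + tn), np.nan)
    undefined = [class_order[i] for i in range(K)
                 if np.isnan(recall[i]) or np.isnan(specificity[i])]
    return EvalReport(
        confusion=confusion,
        class_order=list(class_order),
        recall=recall,
        specificity=specificity,
        accuracy=float(tp.sum() / total),
        macro_recall=float(np.nanmean(recall)),
        macro_specificity=float(np.nanmean(specificity)),
        undefined_classes=undefined,
    )
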