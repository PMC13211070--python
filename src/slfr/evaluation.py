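"""Macro-averaged classification metrics and paired significance testing.

Macro precision/recall/F1 use the 0/0 -> 0 convention for classes that are
never predicted; macro AUC is the unweighted mean of one-vs-rest AUCs over
the classes present in the truth (truth-absent classes are excluded from
the AUC mean but still count as 0 in the precision/recall/F1 means).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (confusion_matrix, precision_recall_fscore_support,
                             roc_auc_score)


@dataclass
class MetricsReport:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    macro_auc: float
    per_class_f1: np.ndarray
    confusion: np.ndarray  # (K, K); rows = true, columns = predicted

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "macro_auc": self.macro_auc,
            "per_class_f1": self.per_class_f1.tolist(),
            "confusion": self.confusion.tolist(),
        }


def compute_metrics(true_labels: np.ndarray, probability_matrix: np.ndarray,
                    n_classes: int | None = None) -> MetricsReport:
    """Metrics from per-record class-probability rows (argmax predictions)."""
    y = np.asarray(true_labels, dtype=int)
    proba = np.asarray(probability_matrix, dtype=float)
    if proba.ndim != 2 or len(y) != len(proba):
        raise ValueError("probability_matrix must be (n_samples, K)")
    row_sums = proba.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > 1e-4):
        bad = int(np.argmax(np.abs(row_sums - 1.0)))
        raise ValueError(f"probability row {bad} sums to {row_sums[bad]:.6f}, "
                         "not 1")
    k = n_classes or proba.shape[1]
    if y.min() < 0 or y.max() >= k:
        raise ValueError(f"labels must lie in [0, {k})")
    preds = proba.argmax(axis=1)
    labels = np.arange(k)
    precision, recall, f1, _ = precision_recall_fscore_support(
        y, preds, labels=labels, average=None, zero_division=0)
    conf = confusion_matrix(y, preds, labels=labels)
    present = np.unique(y)
    aucs = []
    for c in present:
        binary = (y == c).astype(int)
        if binary.all():  # only one class in truth: AUC undefined
            continue
        aucs.append(roc_auc_score(binary, proba[:, c]))
    return MetricsReport(
        accuracy=float((preds == y).mean()),
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        macro_auc=float(np.mean(aucs)) if aucs else float("nan"),
        per_class_f1=f1,
        confusion=conf,
    )


def paired_significance(pred_a: np.ndarray, pred_b: np.ndarray,
                        true_labels: np.ndarray, n_boot: int = 2000,
                        seed: int = 0) -> float:
    """Two-sided paired bootstrap p-value for the accuracy difference.

    Records are resampled with replacement; the p-value is twice the smaller
    tail probability of the bootstrap accuracy-difference distribution
    around zero (add-one smoothed), clipped to [0, 1].
    """
    pred_a = np.asarray(pred_a)
    pred_b = np.asarray(pred_b)
    y = np.asarray(true_labels)
    if not len(pred_a) == len(pred_b) == len(y):
        raise ValueError("prediction vectors and labels must share length")
    correct_a = (pred_a == y).astype(float)
    correct_b = (pred_b == y).astype(float)
    if np.array_equal(pred_a, pred_b):
        return 1.0
    rng = np.random.default_rng(seed)
    n = len(y)
    idx = rng.integers(0, n, size=(n_boot, n))
    diffs = correct_a[idx].mean(axis=1) - correct_b[idx].mean(axis=1)
    lo = (np.sum(diffs <= 0) + 1) / (n_boot + 1)
    hi = (np.sum(diffs >= 0) + 1) / (n_boot + 1)
    return float(min(1.0, 2 * min(lo, hi)))
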