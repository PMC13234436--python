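"""Binary-classification metrics computed from first principles.

All downstream stages (scaler premodeling, cross-cohort runs, panel
evaluation) score models with the same six quantities: accuracy, recall,
precision, F1, the Matthews correlation coefficient (MCC) and the area
under the ROC curve (AUC).  The formulas are written out explicitly from
the confusion counts rather than delegated to a library, because their
edge conventions (0/0 -> 0 for F1 and MCC, mid-rank tie handling for AUC)
are part of the contract and are verified against independent oracles in
the test suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["MetricSet", "compute_metrics", "confusion_counts", "auc_mann_whitney",
           "balanced_accuracy"]


@dataclass(frozen=True)
class MetricSet:
    """The six evaluation metrics of one model on one cohort.

    ``auc`` is ``None`` when the labels contain a single class, in which
    case ranking performance is undefined.
    """

    accuracy: float
    recall: float
    precision: float
    f1: float
    mcc: float
    auc: float | None

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "mcc": self.mcc,
            "auc": self.auc,
        }


def confusion_counts(labels: np.ndarray, predictions: np.ndarray) -> tuple[int, int, int, int]:
    """Return (TP, FP, FN, TN) with class 1 as the positive class."""
    labels = np.asarray(labels).astype(int)
    predictions = np.asarray(predictions).astype(int)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))
    tn = int(np.sum((labels == 0) & (predictions == 0)))
    return tp, fp, fn, tn


def auc_mann_whitney(labels: np.ndarray, scores: np.ndarray) -> float | None:
    """Tie-corrected AUC via the Mann-Whitney U statistic with mid-ranks.

    Equals the probability that a randomly chosen positive outranks a
    randomly chosen negative, with ties counting one half.  Returns ``None``
    (with a warning) when only one class is present.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        warnings.warn("AUC undefined for single-class labels; reporting None")
        return None
    ranks = rankdata(scores, method="average")
    rank_sum_pos = float(np.sum(ranks[labels == 1]))
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def compute_metrics(labels, scores, threshold: float = 0.5) -> MetricSet:
    """Score continuous predictions against binary labels.

    Predictions are thresholded at ``threshold`` (score >= threshold is
    called class 1).  MCC uses the closed form
    ``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))`` with a zero
    denominator mapping to 0; F1 is 0 when precision + recall is 0.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if not np.all(np.isin(labels, [0, 1])):
        raise ValueError("labels must be binary (0/1)")
    preds = (scores >= threshold).astype(int)
    tp, fp, fn, tn = confusion_counts(labels, preds)
    n = tp + fp + fn + tn
    accuracy = (tp + tn) / n if n else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if (precision + recall) else 0.0
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = ((tp * tn - fp * fn) / denom) if denom else 0.0
    auc = auc_mann_whitney(labels, scores)
    return MetricSet(accuracy=accuracy, recall=recall, precision=precision,
                     f1=f1, mcc=mcc, auc=auc)


def balanced_accuracy(labels, predictions) -> float:
    """Mean of sensitivity and specificity; the stepwise-search criterion.

    Used instead of plain accuracy because the pathology cohorts have
    markedly different class balances (25/11 vs 21/34), which plain
    accuracy would reward ignoring.
    """
    tp, fp, fn, tn = confusion_counts(labels, predictions)
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    spec = tn / (tn + fp) if (tn + fp) else 0.0
    return 0.5 * (sens + spec)
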