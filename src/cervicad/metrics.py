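"""Evaluation statistics for slide- and pixel-level grading.

Conventions (each is load-bearing for the reported numbers):

* confusion matrices are stored with rows = predicted class and
  columns = actual class;
* "balanced accuracy" is the unweighted mean of per-actual-class recall
  (macro recall);
* "sensitivity", "precision" and "F1" are support-weighted averages of
  the per-class values, with weights equal to the actual-class supports;
* quadratic weighted kappa (QWK) is computed on integer counts over the
  ordered three-grade scale only -- the unordered "others" class must be
  removed first with :func:`exclude_class`, which drops both the
  predicted row and the actual column of the excluded class.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .labels import OTHERS

__all__ = [
    "ConfusionMatrix",
    "balanced_accuracy",
    "weighted_prf",
    "qwk_statistic",
    "qwk_weight_matrix",
    "exclude_class",
    "segmentation_metrics",
    "detection_balanced_accuracy",
    "macro_ovr_auc",
    "classification_report",
]


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    """Integer count matrix, rows = predicted, columns = actual."""

    counts: np.ndarray
    classes: tuple

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if counts.shape[0] != len(self.classes):
            raise ValueError("class list does not match matrix size")
        if (counts < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "classes", tuple(self.classes))

    @classmethod
    def from_labels(cls, predicted: Sequence, actual: Sequence, classes: Sequence) -> "ConfusionMatrix":
        classes = tuple(classes)
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
        for p, a in zip(predicted, actual, strict=True):
            counts[index[p], index[a]] += 1
        return cls(counts, classes)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def actual_totals(self) -> np.ndarray:
        """Support of each actual class (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def predicted_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def observed(self) -> np.ndarray:
        """Actual-by-predicted orientation (x_{y,yhat}): the transpose."""
        return self.counts.T.copy()

    def to_frame(self):
        import pandas as pd

        names = [str(c) for c in self.classes]
        return pd.DataFrame(self.counts, index=names, columns=names)


def _as_cm(cm) -> ConfusionMatrix:
    if isinstance(cm, ConfusionMatrix):
        return cm
    counts = np.asarray(cm)
    return ConfusionMatrix(counts, tuple(range(counts.shape[0])))


def balanced_accuracy(cm) -> float:
    """Unweighted mean over actual classes of per-class recall."""
    cm = _as_cm(cm)
    supports = cm.actual_totals
    if (supports == 0).any():
        raise ValueError("balanced accuracy undefined: an actual class has no items")
    recalls = np.diag(cm.counts) / supports
    return float(recalls.mean())


def weighted_prf(cm) -> tuple[float, float, float]:
    """Support-weighted (precision, sensitivity, F1).

    Per-class precision = correct / predicted-total and recall =
    correct / actual-total; classes with a zero denominator contribute 0.
    The weighted sensitivity is algebraically the micro accuracy
    (trace / total).
    """
    cm = _as_cm(cm)
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    correct = np.diag(cm.counts).astype(float)
    pred_tot = cm.predicted_totals.astype(float)
    act_tot = cm.actual_totals.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(pred_tot > 0, correct / np.maximum(pred_tot, 1e-300), 0.0)
        recall = np.where(act_tot > 0, correct / np.maximum(act_tot, 1e-300), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)
    w = act_tot / cm.total
    return float(w @ precision), float(w @ recall), float(w @ f1)


def qwk_weight_matrix(n: int) -> np.ndarray:
    """Quadratic disagreement weights w[y, yhat] = (y - yhat)^2 / (n - 1)^2."""
    if n < 2:
        raise ValueError("weight matrix needs at least 2 classes")
    idx = np.arange(n)
    return (idx[:, None] - idx[None, :]) ** 2 / (n - 1) ** 2


def qwk_statistic(cm) -> float:
    """Quadratic weighted kappa on an ordered-class count matrix.

    kappa = 1 - sum(w * x) / sum(w * m), with x the observed counts and
    m the outer product of the marginals normalised to the same total.
    """
    cm = _as_cm(cm)
    if any(c == OTHERS for c in cm.classes):
        raise ValueError("QWK is ordinal; exclude the 'others' class first")
    n = len(cm.classes)
    if n < 2:
        raise ValueError("QWK needs at least 2 classes")
    x = cm.observed().astype(float)  # rows = actual, cols = predicted
    total = x.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    w = qwk_weight_matrix(n)
    m = np.outer(x.sum(axis=1), x.sum(axis=0)) / total
    denom = float((w * m).sum())
    if denom == 0.0:
        return 0.0
    return float(1.0 - (w * x).sum() / denom)


def exclude_class(cm: ConfusionMatrix, cls) -> ConfusionMatrix:
    """Remove one class entirely: both its predicted row and actual column.

    Items of the remaining classes that were predicted as the excluded
    class are dropped from the evaluation (they sit in the removed row).
    """
    cm = _as_cm(cm)
    if cls not in cm.classes:
        raise ValueError(f"class {cls!r} not in confusion matrix")
    i = cm.classes.index(cls)
    keep = [k for k in range(len(cm.classes)) if k != i]
    counts = cm.counts[np.ix_(keep, keep)]
    classes = tuple(cm.classes[k] for k in keep)
    return ConfusionMatrix(counts, classes)


def segmentation_metrics(pred_mask, true_mask) -> dict[str, float]:
    """Pixel-level Dice, IoU, sensitivity, precision and accuracy.

    The empty-vs-empty case is defined as perfect (dice = iou = 1).
    """
    pred = np.asarray(pred_mask).astype(bool)
    true = np.asarray(true_mask).astype(bool)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    tp = int((pred & true).sum())
    fp = int((pred & ~true).sum())
    fn = int((~pred & true).sum())
    tn = int((~pred & ~true).sum())
    dice = 1.0 if (2 * tp + fp + fn) == 0 else 2 * tp / (2 * tp + fp + fn)
    iou = 1.0 if (tp + fp + fn) == 0 else tp / (tp + fp + fn)
    sens = 1.0 if (tp + fn) == 0 else tp / (tp + fn)
    prec = 1.0 if (tp + fp) == 0 else tp / (tp + fp)
    acc = (tp + tn) / max(tp + tn + fp + fn, 1)
    return {"dice": dice, "iou": iou, "sensitivity": sens, "precision": prec, "accuracy": acc}


def detection_balanced_accuracy(predicted_positive: Sequence[bool], actual_positive: Sequence[bool]) -> float:
    """Balanced accuracy of the epithelium-present / non-representative split.

    Mean of positive recall (slides with epithelium detected as such) and
    negative recall ("others" slides left empty by the segmenter).
    """
    pred = np.asarray(predicted_positive, dtype=bool)
    act = np.asarray(actual_positive, dtype=bool)
    if pred.shape != act.shape:
        raise ValueError("length mismatch")
    n_pos = int(act.sum())
    n_neg = int((~act).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both positive and negative slides are required")
    tpr = (pred & act).sum() / n_pos
    tnr = (~pred & ~act).sum() / n_neg
    return float((tpr + tnr) / 2)


def macro_ovr_auc(scores, actual_index) -> float:
    """One-vs-rest macro AUC over class score columns (rank-based).

    Provided for completeness when per-item scores are available; not part
    of the worked-example surface.
    """
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    actual = np.asarray(actual_index, dtype=int)
    aucs = []
    for k in range(scores.shape[1]):
        pos = actual == k
        n_pos = int(pos.sum())
        n_neg = len(actual) - n_pos
        if n_pos == 0 or n_neg == 0:
            continue
        r = rankdata(scores[:, k])
        auc = (r[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        aucs.append(auc)
    if not aucs:
        raise ValueError("AUC undefined: need both positives and negatives")
    return float(np.mean(aucs))


def classification_report(cm: ConfusionMatrix) -> dict:
    """Bundle of every slide-level statistic, as a JSON-serialisable dict.

    Unlike the strict :func:`balanced_accuracy`, the report averages
    recall over the actual classes that are present, so cohorts missing a
    class still evaluate.
    """
    cm = _as_cm(cm)
    precision, sensitivity, f1 = weighted_prf(cm)
    supports = cm.actual_totals
    present = supports > 0
    recalls = np.diag(cm.counts)[present] / supports[present]
    report = {
        "classes": [str(c) for c in cm.classes],
        "confusion_matrix": cm.counts.tolist(),
        "n": cm.total,
        "balanced_accuracy": float(recalls.mean()),
        "precision_weighted": precision,
        "sensitivity_weighted": sensitivity,
        "f1_weighted": f1,
    }
    if not any(c == OTHERS for c in cm.classes):
        report["qwk"] = qwk_statistic(cm)
    return report
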