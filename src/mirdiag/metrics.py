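"""Single-marker diagnostic value: mutual information, threshold
sensitivity/specificity, and the ROC curve of an individual miRNA.

Mutual information (MI) is computed between the class label and the marker
dichotomized at a threshold.  By default the threshold maximizing MI over
all midpoints between adjacent observed values is used; MI is reported in
bits and is bounded above by the entropy of the class label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "MarkerInfo",
    "mutual_information",
    "threshold_metrics",
    "single_marker_roc",
    "marker_info",
]


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    return classes


def _entropy_bits(counts: np.ndarray) -> float:
    counts = counts[counts > 0].astype(float)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _table_mi_bits(table: np.ndarray) -> float:
    """Plug-in mutual information of a 2x2 contingency table, in bits."""
    n = table.sum()
    if n == 0:
        return 0.0
    h_class = _entropy_bits(table.sum(axis=0))
    h_split = _entropy_bits(table.sum(axis=1))
    h_joint = _entropy_bits(table.ravel())
    return max(0.0, h_class + h_split - h_joint)


def mutual_information(values: np.ndarray, labels: np.ndarray,
                       method: str = "optimal") -> tuple[float, float]:
    """MI (bits) between the class label and the dichotomized marker.

    ``method="optimal"`` scans every midpoint between adjacent sorted
    unique values and returns the maximizing split; ``method="median"``
    splits at the marker median.  A constant marker carries no information
    (MI = 0).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = _check_binary(labels)
    uniq = np.unique(values)
    if uniq.size == 1:
        return 0.0, float(uniq[0])
    if method == "median":
        thresholds = [float(np.median(values))]
    elif method == "optimal":
        thresholds = list((uniq[:-1] + uniq[1:]) / 2.0)
    else:
        raise ValueError(f"unknown method {method!r}")

    y = labels == classes[1]
    best_mi, best_thr = -1.0, thresholds[0]
    for thr in thresholds:
        hi = values > thr
        table = np.array([[np.sum(hi & y), np.sum(hi & ~y)],
                          [np.sum(~hi & y), np.sum(~hi & ~y)]], dtype=float)
        mi = _table_mi_bits(table)
        if mi > best_mi:
            best_mi, best_thr = mi, float(thr)
    return best_mi, best_thr


def threshold_metrics(values: np.ndarray, labels: np.ndarray,
                      threshold: float, positive_label,
                      positive_high: bool = True) -> tuple[float, float]:
    """Sensitivity and specificity of the marker dichotomized at ``threshold``.

    ``positive_high=True`` predicts the positive (disease) class for values
    above the threshold; ``False`` for values below.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    _check_binary(labels)
    pos = labels == positive_label
    if not pos.any() or pos.all():
        raise ValueError("both classes required")
    call = values > threshold if positive_high else values < threshold
    tp = np.sum(call & pos)
    fn = np.sum(~call & pos)
    tn = np.sum(~call & ~pos)
    fp = np.sum(call & ~pos)
    return float(tp / (tp + fn)), float(tn / (tn + fp))


def single_marker_roc(values: np.ndarray, labels: np.ndarray,
                      positive_label) -> tuple[np.ndarray, float]:
    """ROC curve and AUC of one marker.

    AUC equals the Mann-Whitney probability that a random positive sample
    ranks above a random negative one, ties counted one half.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    _check_binary(labels)
    y = (labels == positive_label).astype(int)
    if y.sum() in (0, len(y)):
        raise ValueError("both classes required")
    fpr, tpr, _ = roc_curve(y, values)
    auc = float(roc_auc_score(y, values))
    return np.column_stack([fpr, tpr]), auc


@dataclass
class MarkerInfo:
    """Summary of one marker's diagnostic value."""

    mirna_id: str
    mi_bits: float
    best_threshold: float
    sensitivity: float
    specificity: float
    auc_single: float


def marker_info(mirna_id: str, values: np.ndarray, labels: np.ndarray,
                positive_label) -> MarkerInfo:
    """MI, optimal-threshold sensitivity/specificity and AUC for one marker.

    The marker's orientation (disease-high vs disease-low) is chosen so
    that sensitivity + specificity is maximal at the MI-optimal split;
    the reported AUC uses the same orientation, so a marker that is
    down-regulated in disease still scores near 1, not near 0.
    """
    mi, thr = mutual_information(values, labels)
    hi = threshold_metrics(values, labels, thr, positive_label, True)
    lo = threshold_metrics(values, labels, thr, positive_label, False)
    positive_high = sum(hi) >= sum(lo)
    sens, spec = hi if positive_high else lo
    scores = np.asarray(values) if positive_high else -np.asarray(values)
    _, auc = single_marker_roc(scores, labels, positive_label)
    return MarkerInfo(mirna_id, mi, thr, sens, spec, auc)
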