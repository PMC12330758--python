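"""Threshold-free and thresholded classifier evaluation metrics.

AUROC is the trapezoidal area under the full-threshold-sweep ROC curve
(equivalent to the pairwise probability that a positive outranks a negative,
ties counting half); average precision is the step integral of the
precision-recall curve.  These are implemented here rather than delegated so
they can be verified against a brute-force pairwise oracle.
"""

from __future__ import annotations

import numpy as np

__all__ = ["roc_curve", "pr_curve", "roc_pr_confusion"]


def _sorted_sweep(y_true: np.ndarray, y_prob: np.ndarray):
    order = np.argsort(-y_prob, kind="mergesort")
    y = y_true[order]
    p = y_prob[order]
    # threshold boundaries: last index of each distinct score
    distinct = np.r_[np.flatnonzero(np.diff(p)), len(p) - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(1 - y)[distinct]
    return tps, fps, p[distinct]


def roc_curve(y_true: np.ndarray, y_prob: np.ndarray):
    """(fpr, tpr, thresholds) over the full threshold sweep."""
    y_true = np.asarray(y_true, dtype=int)
    y_prob = np.asarray(y_prob, dtype=float)
    n_pos = int(y_true.sum())
    n_neg = len(y_true) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("y_true must contain both classes")
    tps, fps, thr = _sorted_sweep(y_true, y_prob)
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return fpr, tpr, np.r_[np.inf, thr]


def pr_curve(y_true: np.ndarray, y_prob: np.ndarray):
    """(recall, precision, thresholds) over the full threshold sweep."""
    y_true = np.asarray(y_true, dtype=int)
    y_prob = np.asarray(y_prob, dtype=float)
    n_pos = int(y_true.sum())
    if n_pos == 0 or n_pos == len(y_true):
        raise ValueError("y_true must contain both classes")
    tps, fps, thr = _sorted_sweep(y_true, y_prob)
    precision = tps / (tps + fps)
    recall = tps / n_pos
    return recall, precision, thr


def roc_pr_confusion(
    y_true: np.ndarray, y_prob: np.ndarray, threshold: float = 0.5
) -> dict:
    """AUROC, average precision and fixed-threshold confusion metrics.

    AUROC by the trapezoid rule over the ROC sweep; average precision as the
    PR step integral  sum (R_k - R_{k-1}) P_k ; accuracy / per-class
    precision / recall and a row-normalized confusion matrix at
    ``threshold``.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_prob = np.asarray(y_prob, dtype=float)
    fpr, tpr, _ = roc_curve(y_true, y_prob)
    auroc = float(np.trapezoid(tpr, fpr))
    recall, precision, _ = pr_curve(y_true, y_prob)
    ap = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))

    y_hat = (y_prob >= threshold).astype(int)
    conf = np.zeros((2, 2), dtype=float)
    for t, h in zip(y_true, y_hat):
        conf[t, h] += 1
    row_sums = conf.sum(axis=1, keepdims=True)
    conf_norm = np.divide(conf, row_sums, out=np.zeros_like(conf), where=row_sums > 0)
    per_class = {}
    for c in (0, 1):
        tp = conf[c, c]
        per_class[c] = {
            "precision": float(tp / conf[:, c].sum()) if conf[:, c].sum() else np.nan,
            "recall": float(tp / conf[c, :].sum()) if conf[c, :].sum() else np.nan,
        }
    return {
        "auroc": auroc,
        "average_precision": ap,
        "accuracy": float((y_hat == y_true).mean()),
        "confusion_normalized": conf_norm,
        "confusion_counts": conf,
        "per_class": per_class,
        "roc": (fpr, tpr),
        "pr": (recall, precision),
    }
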