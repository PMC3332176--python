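"""Pixel-level segmentation scoring: confusion counts, sensitivity and
specificity, ROC curves by threshold sweep, and trapezoidal AUC.

Conventions: score maps are per-pixel lesion probabilities in [0, 1]; higher
means more lesion-like; a threshold t produces the mask ``score >= t``
(closed at the threshold).  Sensitivity = TP / (TP + FN) is the fraction of
lesion pixels recovered; specificity = TN / (FP + TN) the fraction of skin
pixels rejected.  Ratios with an empty class come back as NaN rather than
raising so batch tables stay rectangular.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "ROCCurve",
    "confusion",
    "sensitivity_specificity",
    "roc_curve",
    "evaluate_batch",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _as_binary(arr: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(arr)
    vals = np.unique(a)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} must be binary (0/1), found values {vals[:8]}")
    return a.astype(bool)


def confusion(mask: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Count TP/FP/TN/FN of a predicted mask against ground truth (1 = lesion)."""
    m = _as_binary(mask, "mask")
    g = _as_binary(gt, "ground truth")
    if m.shape != g.shape:
        raise ValueError(f"shape mismatch: mask {m.shape} vs ground truth {g.shape}")
    return ConfusionCounts(
        tp=int((m & g).sum()),
        fp=int((m & ~g).sum()),
        tn=int((~m & ~g).sum()),
        fn=int((~m & g).sum()),
    )


def sensitivity_specificity(c: ConfusionCounts) -> tuple[float, float]:
    """(TP/(TP+FN), TN/(FP+TN)); NaN for an empty class."""
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else float("nan")
    spec = c.tn / (c.fp + c.tn) if (c.fp + c.tn) > 0 else float("nan")
    return sens, spec


@dataclass
class ROCCurve:
    thresholds: np.ndarray  # decreasing
    fpr: np.ndarray  # anchored: starts at 0, ends at 1
    tpr: np.ndarray
    auc: float


def roc_curve(
    score: np.ndarray,
    gt: np.ndarray,
    n_thresholds: int | None = None,
) -> ROCCurve:
    """ROC by sweeping the classification threshold from the most positive
    score to the most negative.

    Thresholds are the unique score values (or ``n_thresholds`` quantiles
    when there are more unique values than that); each threshold t yields the
    mask ``score >= t`` and one (FPR, TPR) point.  (0, 0) and (1, 1) anchors
    are appended and the AUC is the trapezoidal area.  Raises if the ground
    truth contains a single class.
    """
    s = np.asarray(score, dtype=float).ravel()
    g = _as_binary(gt, "ground truth").ravel()
    if s.shape != g.shape:
        raise ValueError("score and ground truth shapes differ")
    n_pos, n_neg = int(g.sum()), int((~g).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ground truth must contain both lesion and skin pixels")

    thresholds = np.unique(s)[::-1]
    if n_thresholds is not None and thresholds.size > n_thresholds:
        thresholds = np.unique(np.quantile(s, np.linspace(0, 1, n_thresholds)))[::-1]

    # mask(t) = score >= t: cumulative class counts over descending scores
    order = np.argsort(-s, kind="stable")
    s_sorted, g_sorted = s[order], g[order]
    cum_tp = np.cumsum(g_sorted)
    cum_fp = np.cumsum(~g_sorted)
    # index of the last score >= t in the sorted array, per threshold
    last = s_sorted.size - np.searchsorted(s_sorted[::-1], thresholds, side="left") - 1
    valid = last >= 0
    tpr = np.where(valid, cum_tp[np.maximum(last, 0)], 0) / n_pos
    fpr = np.where(valid, cum_fp[np.maximum(last, 0)], 0) / n_neg

    fpr = np.concatenate([[0.0], fpr, [1.0]])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def evaluate_batch(
    pairs: Iterable[tuple[np.ndarray, np.ndarray]],
    labels: Sequence[str] | None = None,
    methods: Sequence[str] | None = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Score a batch of (score map, ground truth) pairs.

    Returns one row per pair with sensitivity and specificity at the default
    threshold plus the swept-threshold AUC, mirroring a per-image results
    table.  Columns: image, method, sensitivity, specificity, auc.
    """
    rows = []
    pairs = list(pairs)
    if not pairs:
        raise ValueError("need at least one (score, ground truth) pair")
    for i, (score, gt) in enumerate(pairs):
        name = labels[i] if labels is not None else f"image_{i}"
        method = methods[i] if methods is not None else ""
        mask = (np.asarray(score, dtype=float) >= threshold).astype(int)
        sens, spec = sensitivity_specificity(confusion(mask, gt))
        auc = roc_curve(score, gt).auc
        rows.append(
            {"image": name, "method": method, "sensitivity": sens,
             "specificity": spec, "auc": auc}
        )
    return pd.DataFrame(rows)
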