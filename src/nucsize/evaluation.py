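"""Segmentation and classification quality measures.

Covers the three levels at which a mask-based workflow is judged:
pixel-level binary agreement (Dice similarity coefficient), object-level
detection (one-to-one IoU matching with precision/recall/F1), and
image-level classification (confusion matrix and accuracy).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

from nucsize.mask_io import validate_binary_mask, validate_instance_mask


def dice_score(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice similarity coefficient 2|X∩Y| / (|X|+|Y|) of two binary masks.

    Defined as 1.0 when both masks are empty (perfect agreement on nothing).
    """
    p = validate_binary_mask(pred).astype(bool)
    t = validate_binary_mask(truth).astype(bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & t).sum()) / denom


@dataclass(frozen=True)
class MatchResult:
    """One-to-one matching of predicted against ground-truth objects."""

    true_positives: int
    false_positives: int
    false_negatives: int
    pairs: tuple[tuple[int, int, float], ...]  # (gt_label, pred_label, IoU)
    degenerate: bool = False  # a zero denominator was reported as 0

    @property
    def precision(self) -> float:
        denom = self.true_positives + self.false_positives
        return self.true_positives / denom if denom else 0.0

    @property
    def recall(self) -> float:
        denom = self.true_positives + self.false_negatives
        return self.true_positives / denom if denom else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def _pairwise_iou(pred: np.ndarray, truth: np.ndarray) -> dict[tuple[int, int], float]:
    """IoU for every (gt_label, pred_label) pair with nonzero overlap."""
    both = (truth > 0) & (pred > 0)
    t, p = truth[both].astype(np.int64), pred[both].astype(np.int64)
    keys = t * (int(pred.max()) + 1) + p
    uniq, inter = np.unique(keys, return_counts=True)
    t_area = np.bincount(truth.ravel())
    p_area = np.bincount(pred.ravel())
    out = {}
    for key, n in zip(uniq, inter):
        gt, pr = int(key) // (int(pred.max()) + 1), int(key) % (int(pred.max()) + 1)
        union = t_area[gt] + p_area[pr] - n
        out[(gt, pr)] = float(n / union)
    return out


def match_objects(
    pred: np.ndarray, truth: np.ndarray, iou_threshold: float = 0.5
) -> MatchResult:
    """Greedily match predicted to ground-truth objects by descending IoU.

    Pairs with IoU >= ``iou_threshold`` are matched one-to-one, highest IoU
    first (ties broken by ascending ground-truth then predicted label).
    Unmatched ground-truth objects are false negatives, unmatched
    predictions false positives.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError("iou_threshold must lie in (0, 1)")
    p = validate_instance_mask(pred)
    t = validate_instance_mask(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    n_pred, n_truth = int(p.max()), int(t.max())
    ious = _pairwise_iou(p, t)
    candidates = sorted(
        ((iou, gt, pr) for (gt, pr), iou in ious.items() if iou >= iou_threshold),
        key=lambda x: (-x[0], x[1], x[2]),
    )
    used_gt: set[int] = set()
    used_pr: set[int] = set()
    pairs = []
    for iou, gt, pr in candidates:
        if gt in used_gt or pr in used_pr:
            continue
        used_gt.add(gt)
        used_pr.add(pr)
        pairs.append((gt, pr, iou))
    tp = len(pairs)
    result = MatchResult(
        true_positives=tp,
        false_positives=n_pred - tp,
        false_negatives=n_truth - tp,
        pairs=tuple(pairs),
        degenerate=(n_pred == 0 or n_truth == 0),
    )
    return result


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count matrix; rows are truth, columns are predictions."""

    classes: tuple[str, ...]
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        total = self.total
        if total == 0:
            raise ValueError("accuracy undefined for an empty confusion matrix")
        return float(np.trace(self.counts)) / total


def confusion_and_accuracy(
    truth_labels: Sequence[str], pred_labels: Sequence[str], classes: Sequence[str]
) -> tuple[ConfusionMatrix, float]:
    """Confusion matrix of truth vs. prediction and its overall accuracy."""
    if len(truth_labels) != len(pred_labels):
        raise ValueError("truth and prediction lists must have equal length")
    known = set(classes)
    for lab in (*truth_labels, *pred_labels):
        if lab not in known:
            raise ValueError(f"label {lab!r} not in class list {list(classes)}")
    counts = _sk_confusion_matrix(truth_labels, pred_labels, labels=list(classes))
    cm = ConfusionMatrix(classes=tuple(classes), counts=counts)
    return cm, cm.accuracy
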