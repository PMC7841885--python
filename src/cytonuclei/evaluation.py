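"""Evaluation protocol: per-nucleus Dice, object-level P/R/F1, and AJI.

A predicted nucleus is matched one-to-one to a ground-truth nucleus by
greedy descending pairwise Dice among overlapping pairs; a matched pair
with Dice >= 0.6 is a true positive, any other prediction a false
positive, and any ground-truth nucleus without a qualifying match a false
negative. Precision, recall and F1 follow

    Precision = TP / (TP + FP)
    Recall    = TP / (TP + FN)
    F1        = 2 / (Precision^-1 + Recall^-1)

The Aggregated Jaccard Index (AJI) combines pixel- and object-level
agreement: for each ground-truth instance the not-yet-used prediction
maximising the Jaccard overlap is consumed, intersections accumulate in
the numerator, unions in the denominator, and the pixels of unmatched
predictions are added to the denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "dice",
    "match_instances",
    "prf1",
    "aji",
    "EvaluationResult",
    "evaluate_pair",
    "evaluate_set",
]


def _as_label_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("label masks must be 2-D")
    if mask.min() < 0:
        raise ValueError("label masks must be non-negative")
    return mask.astype(np.int64)


def _relabel(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Re-index labels to the contiguous set 1..K, preserving order."""
    labels = np.unique(mask)
    labels = labels[labels > 0]
    lut = np.zeros(int(mask.max()) + 1, dtype=np.int64)
    lut[labels] = np.arange(1, labels.size + 1)
    return lut[mask], int(labels.size)


def dice(A, B) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|) between two pixel sets.

    ``A`` and ``B`` may be boolean arrays of equal shape or sets/iterables
    of (row, col) tuples. Raises if both are empty.
    """
    if isinstance(A, np.ndarray) and isinstance(B, np.ndarray):
        A_, B_ = A.astype(bool), B.astype(bool)
        if A_.shape != B_.shape:
            raise ValueError("mask shapes differ")
        na, nb = int(A_.sum()), int(B_.sum())
        inter = int((A_ & B_).sum())
    else:
        sa, sb = set(map(tuple, A)), set(map(tuple, B))
        na, nb = len(sa), len(sb)
        inter = len(sa & sb)
    if na + nb == 0:
        raise ValueError("Dice is undefined for two empty sets")
    return 2.0 * inter / (na + nb)


def _overlap_matrix(gt: np.ndarray, pred: np.ndarray, n_gt: int, n_pred: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pixel counts per instance and the (n_gt+1, n_pred+1) co-occurrence table."""
    gt_sizes = np.bincount(gt.ravel(), minlength=n_gt + 1)
    pred_sizes = np.bincount(pred.ravel(), minlength=n_pred + 1)
    pair = gt.ravel() * (n_pred + 1) + pred.ravel()
    inter = np.bincount(pair, minlength=(n_gt + 1) * (n_pred + 1)).reshape(
        n_gt + 1, n_pred + 1
    )
    return gt_sizes, pred_sizes, inter


def match_instances(
    gt: np.ndarray, pred: np.ndarray, dice_threshold: float = 0.6
) -> tuple[int, int, int, list[float]]:
    """Greedy one-to-one Dice matching with the TP gate.

    Returns ``(TP, FP, FN, per_nucleus_dice)`` where ``per_nucleus_dice``
    holds, for each ground-truth instance in label order, the Dice of its
    greedy match (0.0 if unmatched). Conservation holds by construction:
    ``TP + FN`` = number of ground-truth instances and ``TP + FP`` =
    number of predicted instances.
    """
    gt = _as_label_mask(gt)
    pred = _as_label_mask(pred)
    if gt.shape != pred.shape:
        raise ValueError(f"mask shapes differ: {gt.shape} vs {pred.shape}")
    gt, n_gt = _relabel(gt)
    pred, n_pred = _relabel(pred)
    gt_sizes, pred_sizes, inter = _overlap_matrix(gt, pred, n_gt, n_pred)

    pairs = []
    gs, ps = np.nonzero(inter[1:, 1:])
    for g, p in zip(gs + 1, ps + 1):
        d = float(2.0 * inter[g, p] / (gt_sizes[g] + pred_sizes[p]))
        pairs.append((-d, int(g), int(p)))
    pairs.sort()

    matched_dice = [0.0] * n_gt
    used_gt: set[int] = set()
    used_pred: set[int] = set()
    tp = 0
    for negd, g, p in pairs:
        if g in used_gt or p in used_pred:
            continue
        used_gt.add(g)
        used_pred.add(p)
        matched_dice[g - 1] = -negd
        if -negd >= dice_threshold:
            tp += 1
    fp = n_pred - tp
    fn = n_gt - tp
    return tp, fp, fn, matched_dice


def prf1(TP: int, FP: int, FN: int) -> tuple[float, float, float]:
    """Precision, recall and their harmonic mean; NaN where undefined."""
    precision = TP / (TP + FP) if TP + FP > 0 else math.nan
    recall = TP / (TP + FN) if TP + FN > 0 else math.nan
    if math.isnan(precision) or math.isnan(recall):
        f1 = math.nan
    elif precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return precision, recall, f1


def _aji_terms(gt: np.ndarray, pred: np.ndarray) -> tuple[int, int]:
    """(intersection-sum, union-sum) accumulators of the AJI."""
    gt = _as_label_mask(gt)
    pred = _as_label_mask(pred)
    if gt.shape != pred.shape:
        raise ValueError(f"mask shapes differ: {gt.shape} vs {pred.shape}")
    gt, n_gt = _relabel(gt)
    pred, n_pred = _relabel(pred)
    gt_sizes, pred_sizes, inter = _overlap_matrix(gt, pred, n_gt, n_pred)

    used_pred: set[int] = set()
    num = 0
    den = 0
    for g in range(1, n_gt + 1):
        best_p, best_j, best_i = 0, -1.0, 0
        for p in np.nonzero(inter[g, 1:])[0] + 1:
            if int(p) in used_pred:
                continue
            i = int(inter[g, p])
            j = i / (gt_sizes[g] + pred_sizes[p] - i)
            if j > best_j:  # ties keep the lowest predicted label
                best_p, best_j, best_i = int(p), j, i
        if best_p:
            used_pred.add(best_p)
            num += best_i
            den += int(gt_sizes[g] + pred_sizes[best_p] - best_i)
        else:
            den += int(gt_sizes[g])
    for p in range(1, n_pred + 1):
        if p not in used_pred:
            den += int(pred_sizes[p])
    return num, den


def aji(gt: np.ndarray, pred: np.ndarray) -> float:
    """Aggregated Jaccard Index in [0, 1]; raises on an empty ground truth."""
    num, den = _aji_terms(gt, pred)
    if (np.asarray(gt) > 0).sum() == 0:
        raise ValueError("AJI is undefined for an empty ground truth")
    return num / den


@dataclass
class EvaluationResult:
    """Counts and metrics of one image (or a pooled image set)."""

    TP: int
    FP: int
    FN: int
    per_nucleus_dice: list[float] = field(default_factory=list)
    precision: float = math.nan
    recall: float = math.nan
    f1: float = math.nan
    aji: float = math.nan

    def to_dict(self) -> dict:
        return {
            "TP": self.TP,
            "FP": self.FP,
            "FN": self.FN,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "aji": self.aji,
        }


def evaluate_pair(
    gt: np.ndarray, pred: np.ndarray, dice_threshold: float = 0.6
) -> EvaluationResult:
    """Full per-image evaluation of one (ground truth, prediction) mask pair."""
    tp, fp, fn, dices = match_instances(gt, pred, dice_threshold)
    precision, recall, f1 = prf1(tp, fp, fn)
    if (np.asarray(gt) > 0).sum() > 0:
        a = aji(gt, pred)
    else:
        a = math.nan
    return EvaluationResult(
        TP=tp, FP=fp, FN=fn, per_nucleus_dice=dices,
        precision=precision, recall=recall, f1=f1, aji=a,
    )


def evaluate_set(
    gts: Sequence[np.ndarray],
    preds: Sequence[np.ndarray],
    dice_threshold: float = 0.6,
) -> tuple[EvaluationResult, pd.DataFrame]:
    """Evaluate an image set: pooled (micro-averaged) result + per-image table.

    TP/FP/FN are summed across images before computing precision/recall/F1;
    the pooled AJI sums the per-image numerator and denominator terms.
    """
    if len(gts) != len(preds):
        raise ValueError("need equally many ground-truth and predicted masks")
    if len(gts) == 0:
        raise ValueError("empty image set")
    rows = []
    tp = fp = fn = 0
    num = den = 0
    all_dice: list[float] = []
    for i, (g, p) in enumerate(zip(gts, preds)):
        res = evaluate_pair(g, p, dice_threshold)
        rows.append({"image": i, **res.to_dict()})
        tp, fp, fn = tp + res.TP, fp + res.FP, fn + res.FN
        n, d = _aji_terms(g, p)
        num, den = num + n, den + d
        all_dice.extend(res.per_nucleus_dice)
    precision, recall, f1 = prf1(tp, fp, fn)
    pooled = EvaluationResult(
        TP=tp, FP=fp, FN=fn, per_nucleus_dice=all_dice,
        precision=precision, recall=recall, f1=f1,
        aji=(num / den) if den > 0 else math.nan,
    )
    return pooled, pd.DataFrame(rows)
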