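"""Segmentation evaluation metrics.

Per-slice comparison of a predicted binary mask against its ground truth:
pixel confusion counts, true positive rate (sensitivity), true negative rate
(specificity), Dice-Sørensen coefficient

    DSC = 2 |Sg ∩ Sp| / (|Sg| + |Sp|)

and the symmetric Hausdorff distance

    HD(A, B) = max(h(A, B), h(B, A)),   h(A, B) = max_{a∈A} min_{b∈B} ||a - b||₂

computed on the foreground pixel coordinate sets in pixel units.  Metrics
whose denominator is empty (e.g. DSC of two empty masks, HD against an empty
prediction) are flagged undefined (NaN) and excluded from cohort means with a
logged count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _check_masks(pred: np.ndarray, gt: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {gt.shape}")
    for name, m in (("pred", pred), ("gt", gt)):
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} mask must be binary (values in {{0, 1}})")
    return pred.astype(bool), gt.astype(bool)


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Pixelwise contingency counts of prediction vs ground truth."""
    p, g = _check_masks(pred, gt)
    tp = int(np.sum(p & g))
    fp = int(np.sum(p & ~g))
    fn = int(np.sum(~p & g))
    tn = int(np.sum(~p & ~g))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def tpr(c: ConfusionCounts) -> float:
    """TP / (TP + FN); NaN when the ground truth has no foreground."""
    denom = c.tp + c.fn
    return c.tp / denom if denom else math.nan


def tnr(c: ConfusionCounts) -> float:
    """TN / (TN + FP); NaN when the ground truth has no background."""
    denom = c.tn + c.fp
    return c.tn / denom if denom else math.nan


def dsc(pred: np.ndarray, gt: np.ndarray) -> float:
    """Dice-Sørensen coefficient 2·TP / (|gt| + |pred|); NaN if both are empty."""
    p, g = _check_masks(pred, gt)
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return math.nan
    return 2.0 * int(np.sum(p & g)) / denom


def _as_points(a) -> np.ndarray:
    pts = np.asarray(a, dtype=np.float64)
    if pts.ndim != 2:
        raise ValueError("point sets must be (n, d) arrays")
    return pts


def directed_hausdorff(a, b) -> float:
    """h(A, B): the largest distance from a point of A to its nearest point of B."""
    pa, pb = _as_points(a), _as_points(b)
    if len(pa) == 0 or len(pb) == 0:
        return math.nan
    d, _ = cKDTree(pb).query(pa, k=1)
    return float(np.max(d))


def hausdorff(a, b) -> float:
    """Symmetric Hausdorff distance max(h(A, B), h(B, A))."""
    h_ab = directed_hausdorff(a, b)
    h_ba = directed_hausdorff(b, a)
    if math.isnan(h_ab) or math.isnan(h_ba):
        return math.nan
    return max(h_ab, h_ba)


def mask_points(mask: np.ndarray) -> np.ndarray:
    """Foreground pixel coordinates of a binary mask, as an (n, ndim) array."""
    return np.argwhere(np.asarray(mask).astype(bool))


def hausdorff_masks(pred: np.ndarray, gt: np.ndarray) -> float:
    """Symmetric HD between the foreground pixel sets of two masks (pixel units)."""
    p, g = _check_masks(pred, gt)
    return hausdorff(mask_points(p), mask_points(g))


@dataclass
class SegMetricsReport:
    """Per-pair metrics and their cohort (arithmetic) means.

    Undefined per-pair values are NaN; means exclude them, and
    ``n_undefined`` records how many pairs were excluded per metric.
    """

    per_pair: List[Dict[str, float]] = field(default_factory=list)
    mean: Dict[str, float] = field(default_factory=dict)
    n_undefined: Dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.per_pair)


def evaluate_pair(pred: np.ndarray, gt: np.ndarray) -> Dict[str, float]:
    c = confusion_counts(pred, gt)
    return {"tpr": tpr(c), "tnr": tnr(c), "dsc": dsc(pred, gt), "hd": hausdorff_masks(pred, gt)}


def evaluate_cohort(pairs: Sequence[Tuple[np.ndarray, np.ndarray]]) -> SegMetricsReport:
    """Evaluate a list of (prediction, ground-truth) mask pairs.

    Means are arithmetic over per-pair values; pairs with an undefined metric
    are excluded from that metric's mean, with the count logged.
    """
    if len(pairs) == 0:
        raise ValueError("evaluate_cohort requires at least one pair")
    report = SegMetricsReport()
    for pred, gt in pairs:
        report.per_pair.append(evaluate_pair(pred, gt))
    for key in ("tpr", "tnr", "dsc", "hd"):
        vals = np.array([m[key] for m in report.per_pair], dtype=float)
        defined = vals[~np.isnan(vals)]
        report.n_undefined[key] = int(np.isnan(vals).sum())
        report.mean[key] = float(defined.mean()) if defined.size else math.nan
        if report.n_undefined[key]:
            logger.info("evaluate_cohort: %d pair(s) excluded from mean %s (undefined)",
                        report.n_undefined[key], key)
    return report
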