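"""Segmentation evaluation: Dice, Jaccard, precision, recall and HD95 (mm).

HD95 here is the 95th percentile (linear interpolation between order
statistics) of the *pooled* bidirectional surface-to-surface distance
multiset, which makes it symmetric by construction.  Surface voxels are mask
voxels with at least one 6-connected face neighbour outside the mask, where
the grid border counts as outside; distances are Euclidean millimetre
distances between surface-voxel centres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import FOREGROUND_LABELS, LabelMask


@dataclass
class ClassMetrics:
    dice: float
    jaccard: float
    precision: float
    recall: float
    hd95_mm: float | None  # None when undefined (an empty mask)
    hd95_reason: str | None = None


@dataclass
class EvalReport:
    per_class: dict[int, ClassMetrics]
    mean_dice: float
    mean_jaccard: float
    mean_precision: float
    mean_recall: float
    mean_hd95_mm: float | None
    n_subjects: int = 1


def overlap_metrics(pred: np.ndarray, gt: np.ndarray
                    ) -> tuple[float, float, float, float]:
    """Dice, Jaccard, precision and recall for two aligned binary masks.

    Both empty: all four are 1 (perfect vacuous agreement).  Exactly one
    empty: Dice and Jaccard are 0 and the undefined ratio is reported as 0.
    """
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    np_, ng = int(pred.sum()), int(gt.sum())
    if np_ == 0 and ng == 0:
        return 1.0, 1.0, 1.0, 1.0
    inter = int(np.logical_and(pred, gt).sum())
    union = np_ + ng - inter
    dice = 2.0 * inter / (np_ + ng)
    jaccard = inter / union if union else 0.0
    precision = inter / np_ if np_ else 0.0
    recall = inter / ng if ng else 0.0
    return dice, jaccard, precision, recall


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Boolean grid of mask voxels with a 6-neighbour outside the mask.

    The grid border counts as outside, so voxels touching the border are
    surface voxels.
    """
    mask = np.asarray(mask).astype(bool)
    padded = np.pad(mask, 1)
    interior = padded[1:-1, 1:-1, 1:-1].copy()
    for ax in range(3):
        for off in (-1, 1):
            interior &= np.roll(padded, off, axis=ax)[1:-1, 1:-1, 1:-1]
    return mask & ~interior


def hd95(pred: np.ndarray, gt: np.ndarray,
         spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> float:
    """95th percentile of pooled bidirectional surface distances, in mm."""
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    if not pred.any() or not gt.any():
        raise ValueError("hd95 undefined: at least one mask is empty")
    sp = np.asarray(spacing_mm, float)
    pa = np.argwhere(surface_voxels(pred)) * sp
    ga = np.argwhere(surface_voxels(gt)) * sp
    d_pg = cKDTree(ga).query(pa, k=1)[0]
    d_gp = cKDTree(pa).query(ga, k=1)[0]
    pooled = np.concatenate([d_pg, d_gp])
    return float(np.percentile(pooled, 95, method="linear"))


def jaccard_from_dice(dice: float) -> float:
    return dice / (2.0 - dice)


def evaluate_segmentation(pred: LabelMask | np.ndarray, gt: LabelMask | np.ndarray,
                          spacing_mm: tuple[float, float, float] | None = None
                          ) -> EvalReport:
    """Per-foreground-class overlap and surface metrics for one subject."""
    if isinstance(pred, LabelMask):
        spacing_mm = spacing_mm or pred.spacing_mm
        pred = pred.grid
    if isinstance(gt, LabelMask):
        spacing_mm = spacing_mm or gt.spacing_mm
        gt = gt.grid
    spacing_mm = spacing_mm or (1.0, 1.0, 1.0)
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError("prediction and ground truth shapes differ")
    present = set(np.unique(pred)) | set(np.unique(gt))
    if not present & set(FOREGROUND_LABELS):
        raise ValueError("no foreground labels in {1..4} present in either mask")

    per_class: dict[int, ClassMetrics] = {}
    for c in FOREGROUND_LABELS:
        p, g = pred == c, gt == c
        dice, jac, prec, rec = overlap_metrics(p, g)
        if p.any() and g.any():
            h, reason = hd95(p, g, spacing_mm), None
        else:
            h, reason = None, "empty mask for class"
        per_class[c] = ClassMetrics(dice, jac, prec, rec, h, reason)

    hs = [m.hd95_mm for m in per_class.values() if m.hd95_mm is not None]
    return EvalReport(
        per_class=per_class,
        mean_dice=float(np.mean([m.dice for m in per_class.values()])),
        mean_jaccard=float(np.mean([m.jaccard for m in per_class.values()])),
        mean_precision=float(np.mean([m.precision for m in per_class.values()])),
        mean_recall=float(np.mean([m.recall for m in per_class.values()])),
        mean_hd95_mm=float(np.mean(hs)) if hs else None,
        n_subjects=1,
    )


def aggregate_reports(reports: list[EvalReport]):
    """Cohort table: per-class and mean Dice/HD95 as mean +/- SD DataFrame."""
    import pandas as pd

    rows = []
    for c in FOREGROUND_LABELS:
        dices = [r.per_class[c].dice for r in reports]
        hds = [r.per_class[c].hd95_mm for r in reports
               if r.per_class[c].hd95_mm is not None]
        rows.append({
            "class": c,
            "dice_mean": float(np.mean(dices)),
            "dice_sd": float(np.std(dices)),
            "hd95_mm_mean": float(np.mean(hds)) if hds else math.nan,
            "hd95_mm_sd": float(np.std(hds)) if hds else math.nan,
            "n": len(reports),
        })
    rows.append({
        "class": "mean",
        "dice_mean": float(np.mean([r.mean_dice for r in reports])),
        "dice_sd": float(np.std([r.mean_dice for r in reports])),
        "hd95_mm_mean": float(np.mean([r.mean_hd95_mm for r in reports
                                       if r.mean_hd95_mm is not None])),
        "hd95_mm_sd": float(np.std([r.mean_hd95_mm for r in reports
                                    if r.mean_hd95_mm is not None])),
        "n": len(reports),
    })
    return pd.DataFrame(rows)


__all__ = [
    "ClassMetrics", "EvalReport", "overlap_metrics", "surface_voxels", "hd95",
    "jaccard_from_dice", "evaluate_segmentation", "aggregate_reports",
]
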