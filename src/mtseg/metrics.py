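"""BraTS-convention evaluation over the nested regions ET / WT / TC.

Regions are derived from label volumes over {0, 1, 2, 4}: enhancing
tumor ET = {4}, tumor core TC = {1, 4}, whole tumor WT = {1, 2, 4}, so
ET ⊆ TC ⊆ WT.  Metrics follow the challenge definitions:

    Dice        = 2 TP / (FN + FP + 2 TP)
    Sensitivity = TP / (TP + FN)
    Specificity = TN / (TN + FP)
    HD95        = max over both directions of the 95th percentile of
                  voxel-to-nearest-voxel distances

with the challenge's empty-ET conventions (both masks empty → Dice 1;
ground truth empty but prediction not → Dice 0) and the enhancing-tumor
post-processing rule: when a prediction contains fewer than 500 ET
voxels, all of them are relabeled tumor core (necrosis), which leaves
the WT and TC binary masks unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "REGIONS",
    "ConfusionCounts",
    "region_binarize",
    "confusion_counts",
    "dice_score",
    "sensitivity_specificity",
    "hausdorff95",
    "postprocess_enhancing_tumor",
    "case_metrics",
    "metrics_table",
]

REGIONS = {"ET": (4,), "TC": (1, 4), "WT": (1, 2, 4)}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def region_binarize(labels: np.ndarray, region: str) -> np.ndarray:
    """Binary mask of one evaluation region (ET={4}, TC={1,4}, WT={1,2,4})."""
    try:
        values = REGIONS[region.upper()]
    except KeyError:
        raise ValueError(f"unknown region {region!r}; expected one of {sorted(REGIONS)}") from None
    return np.isin(np.asarray(labels), values)


def confusion_counts(gt: np.ndarray, pred: np.ndarray) -> ConfusionCounts:
    gt = np.asarray(gt, dtype=bool)
    pred = np.asarray(pred, dtype=bool)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: gt {gt.shape} vs pred {pred.shape}")
    tp = int(np.count_nonzero(gt & pred))
    fp = int(np.count_nonzero(~gt & pred))
    fn = int(np.count_nonzero(gt & ~pred))
    tn = int(np.count_nonzero(~gt & ~pred))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def dice_score(counts: ConfusionCounts, gt_empty: bool | None = None, pred_empty: bool | None = None) -> float:
    """Dice with the challenge's empty-region conventions."""
    if gt_empty is None:
        gt_empty = counts.tp + counts.fn == 0
    if pred_empty is None:
        pred_empty = counts.tp + counts.fp == 0
    if gt_empty and pred_empty:
        return 1.0
    if gt_empty:
        return 0.0
    denom = counts.fn + counts.fp + 2 * counts.tp
    return 2.0 * counts.tp / denom if denom else 0.0


def sensitivity_specificity(counts: ConfusionCounts) -> tuple[float, float]:
    """(TP/(TP+FN), TN/(TN+FP)); NaN marks an undefined denominator."""
    sens = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else math.nan
    spec = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else math.nan
    return sens, spec


def hausdorff95(
    gt: np.ndarray,
    pred: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    percentile: float = 95.0,
) -> float:
    """Robust Hausdorff distance between two binary volumes.

    95th percentile (linear interpolation) of directed nearest-neighbor
    distances, symmetrized by the maximum of the two directions.  NaN
    when either mask is empty (excluded from aggregates downstream).
    """
    gt = np.asarray(gt, dtype=bool)
    pred = np.asarray(pred, dtype=bool)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: gt {gt.shape} vs pred {pred.shape}")
    if not gt.any() or not pred.any():
        return math.nan
    # Distance field to the nearest voxel of each mask, sampled at the other.
    dist_to_pred = ndimage.distance_transform_edt(~pred, sampling=spacing)
    dist_to_gt = ndimage.distance_transform_edt(~gt, sampling=spacing)
    d_gp = np.percentile(dist_to_pred[gt], percentile)
    d_pg = np.percentile(dist_to_gt[pred], percentile)
    return float(max(d_gp, d_pg))


def postprocess_enhancing_tumor(pred: np.ndarray, threshold: int = 500) -> np.ndarray:
    """Relabel all ET voxels as tumor core when fewer than ``threshold`` exist.

    Applied to predictions only; compensates for the Dice-0 penalty on
    spurious enhancing voxels in cases whose ground truth has no ET.
    Strict inequality: exactly ``threshold`` ET voxels are kept.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    pred = np.asarray(pred)
    bad = np.setdiff1d(np.unique(pred), (0, 1, 2, 4))
    if bad.size:
        raise ValueError(f"unexpected label values {bad.tolist()}")
    out = pred.copy()
    et = out == 4
    if 0 < int(et.sum()) < threshold:
        out[et] = 1  # necrosis: the TC label that is not ET, so TC/WT are unchanged
    return out


def case_metrics(
    gt_labels: np.ndarray,
    pred_labels: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> dict[str, dict[str, float]]:
    """Per-region Dice / sensitivity / specificity / HD95 and confusion counts."""
    out: dict[str, dict[str, float]] = {}
    for region in REGIONS:
        g = region_binarize(gt_labels, region)
        p = region_binarize(pred_labels, region)
        counts = confusion_counts(g, p)
        sens, spec = sensitivity_specificity(counts)
        out[region] = {
            "dice": dice_score(counts),
            "sensitivity": sens,
            "specificity": spec,
            "hausdorff95": hausdorff95(g, p, spacing=spacing),
            "tp": counts.tp,
            "fp": counts.fp,
            "fn": counts.fn,
            "tn": counts.tn,
        }
    return out


def metrics_table(per_case: dict[str, dict[str, dict[str, float]]]) -> pd.DataFrame:
    """Long-format table (case × region rows) with mean/median summary rows.

    NaN metric values (undefined HD95 or sensitivity on empty regions)
    are excluded from the summary aggregates.
    """
    rows = []
    for case_id, regions in per_case.items():
        for region, vals in regions.items():
            rows.append({"case_id": case_id, "region": region} | vals)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    metric_cols = ["dice", "sensitivity", "specificity", "hausdorff95"]
    summaries = []
    for region, grp in df.groupby("region"):
        for stat, fn in (("mean", np.nanmean), ("median", np.nanmedian)):
            row = {"case_id": f"__{stat}__", "region": region}
            for m in metric_cols:
                vals = grp[m].to_numpy(dtype=float)
                row[m] = float(fn(vals)) if np.isfinite(vals).any() else math.nan
            summaries.append(row)
    return pd.concat([df, pd.DataFrame(summaries)], ignore_index=True)
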