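"""Segmentation evaluation: overlap metrics, surface distances, region reports.

Overlap metrics (Dice, Jaccard, precision, recall/sensitivity, specificity,
F1) are computed from exhaustive per-pixel confusion counts.  Surface
distances (HD95, ASSD) use boundary pixels — foreground pixels with at least
one background 4-neighbour (pixels on the image border count as boundary) —
and the exact Euclidean distance transform, scaled by the physical voxel
spacing so the results are in millimetres.

Zero-denominator conventions (the usual BraTS-style ones): when prediction
and reference are both empty, overlap scores are 1 and distances 0; when
exactly one is empty, overlap scores are 0 and distances are undefined
(returned as NaN and excluded from aggregate means).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import REGION_ORDER, derive_regions

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "overlap_metrics",
    "surface_pixels",
    "hd95",
    "assd",
    "evaluate_regions",
]

OVERLAP_COLUMNS = ["dice", "jaccard", "sensitivity", "specificity",
                   "precision", "f1"]
ALL_COLUMNS = OVERLAP_COLUMNS + ["hd95_mm", "assd_mm"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _as_binary(arr, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return arr.astype(bool)


def confusion_counts(pred, gt) -> ConfusionCounts:
    """Exhaustive pixel tally of TP/FP/FN/TN between two binary grids."""
    pred = _as_binary(pred, "pred")
    gt = _as_binary(gt, "gt")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    tn = int(np.count_nonzero(~pred & ~gt))
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: int, den: int, empty_value: float) -> float:
    return num / den if den > 0 else empty_value


def overlap_metrics(c: ConfusionCounts) -> dict:
    """Dice/Jaccard/precision/recall/specificity/F1 from confusion counts.

    Both-empty masks (tp+fp+fn == 0) score 1 by convention.
    """
    both_empty = (c.tp + c.fp + c.fn) == 0
    dice = _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, 1.0)
    jaccard = _ratio(c.tp, c.tp + c.fp + c.fn, 1.0)
    precision = _ratio(c.tp, c.tp + c.fp, 1.0 if both_empty else 0.0)
    recall = _ratio(c.tp, c.tp + c.fn, 1.0 if both_empty else 0.0)
    specificity = _ratio(c.tn, c.tn + c.fp, 1.0)
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else (1.0 if both_empty else 0.0))
    return {"dice": dice, "jaccard": jaccard, "sensitivity": recall,
            "specificity": specificity, "precision": precision, "f1": f1}


def surface_pixels(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with >= 1 background 4-neighbour (border included)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    cross = ndimage.generate_binary_structure(mask.ndim, 1)
    interior = ndimage.binary_erosion(mask, structure=cross, border_value=0)
    return mask & ~interior


def _directed_surface_distances(src: np.ndarray, dst: np.ndarray,
                                spacing) -> np.ndarray:
    """Distances from each surface pixel of ``src`` to ``dst``'s surface."""
    dt = ndimage.distance_transform_edt(~dst, sampling=spacing)
    return dt[src]


def _surface_setup(pred, gt, spacing):
    pred = _as_binary(pred, "pred")
    gt = _as_binary(gt, "gt")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    if spacing is None:
        spacing = (1.0,) * pred.ndim
    spacing = tuple(float(s) for s in np.atleast_1d(spacing))
    if len(spacing) != pred.ndim:
        raise ValueError("spacing length must match mask dimensionality")
    return pred, gt, spacing


def hd95(pred, gt, spacing=None) -> float:
    """95th-percentile symmetric Hausdorff distance in mm.

    ``max(P95(pred->gt), P95(gt->pred))`` over boundary-pixel distances,
    percentile with linear interpolation.  Both masks empty -> 0.0; exactly
    one empty -> NaN (undefined).
    """
    pred, gt, spacing = _surface_setup(pred, gt, spacing)
    if not pred.any() and not gt.any():
        return 0.0
    if not pred.any() or not gt.any():
        return float("nan")
    sp, sg = surface_pixels(pred), surface_pixels(gt)
    d_pg = _directed_surface_distances(sp, sg, spacing)
    d_gp = _directed_surface_distances(sg, sp, spacing)
    return float(max(np.percentile(d_pg, 95), np.percentile(d_gp, 95)))


def assd(pred, gt, spacing=None) -> float:
    """Average symmetric surface distance in mm (empty conventions as hd95)."""
    pred, gt, spacing = _surface_setup(pred, gt, spacing)
    if not pred.any() and not gt.any():
        return 0.0
    if not pred.any() or not gt.any():
        return float("nan")
    sp, sg = surface_pixels(pred), surface_pixels(gt)
    d_pg = _directed_surface_distances(sp, sg, spacing)
    d_gp = _directed_surface_distances(sg, sp, spacing)
    return float((d_pg.sum() + d_gp.sum()) / (d_pg.size + d_gp.size))


@dataclass
class MetricReport:
    """Per-region metric table (rows WT/TC/ET plus an 'Average' mean row)."""

    table: pd.DataFrame
    n_undefined_surface: int = 0

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="region")

    def to_json(self, path=None):
        payload = {"regions": {r: self.table.loc[r].to_dict()
                               for r in self.table.index},
                   "n_undefined_surface": self.n_undefined_surface}
        if path is None:
            return payload
        import json
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def __getitem__(self, region: str) -> pd.Series:
        return self.table.loc[region]


def evaluate_regions(pred_labels, gt_labels, spacing=None) -> MetricReport:
    """Region-wise (WT/TC/ET) overlap + surface metrics between label maps.

    The aggregate 'Average' row is the arithmetic mean over regions; surface
    distances that are undefined (one mask empty) are excluded from the mean
    and counted in ``n_undefined_surface``.
    """
    pred_regions = derive_regions(pred_labels)
    gt_regions = derive_regions(gt_labels)
    rows, n_undef = {}, 0
    for region in REGION_ORDER:
        p, g = pred_regions[region], gt_regions[region]
        row = overlap_metrics(confusion_counts(p, g))
        row["hd95_mm"] = hd95(p, g, spacing)
        row["assd_mm"] = assd(p, g, spacing)
        n_undef += int(np.isnan(row["hd95_mm"]))
        rows[region] = row
    table = pd.DataFrame(rows).T[ALL_COLUMNS]
    table.loc["Average"] = table.mean(axis=0, skipna=True)
    return MetricReport(table=table, n_undefined_surface=n_undef)
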