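"""Segmentation metrics and their distinct/completed decomposition.

Standard per-class metrics (Dice, 95th-percentile Hausdorff distance,
normalized surface distance) plus the border true-positive decomposition:
the share of reference-border voxels recovered by a prediction, split by
whether the reference voxel is distinct or completed.  The decomposition
is additive by construction: ``tp_distinct + tp_completed = tp_total``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np
from scipy import ndimage

from .borders import BorderSplit
from .edges import check_same_grid

logger = logging.getLogger("usborder")


class UndefinedMetricError(ValueError):
    """A metric was requested on input (e.g. an empty mask) where it is undefined."""


def _surface(mask: np.ndarray) -> np.ndarray:
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~interior


def dice(pred: np.ndarray, gt: np.ndarray) -> float:
    """Dice overlap 2|P∩G|/(|P|+|G|); two empty masks score 1.0."""
    check_same_grid(pred, gt)
    p, g = np.count_nonzero(pred), np.count_nonzero(gt)
    if p + g == 0:
        return 1.0
    return 2.0 * np.count_nonzero(pred & gt) / (p + g)


def _surface_distances(pred: np.ndarray, gt: np.ndarray, spacing):
    """Pooled symmetric surface-to-surface distances in mm (both directions)."""
    check_same_grid(pred, gt)
    if not pred.any() or not gt.any():
        raise UndefinedMetricError("surface distance undefined for an empty mask")
    spacing = tuple(float(s) for s in spacing)
    sp, sg = _surface(pred), _surface(gt)
    # EDT of the complement gives distance-to-surface at every voxel
    dt_g = ndimage.distance_transform_edt(~sg, sampling=spacing)
    dt_p = ndimage.distance_transform_edt(~sp, sampling=spacing)
    return dt_g[sp], dt_p[sg]


def hd95(pred: np.ndarray, gt: np.ndarray, spacing=None) -> float:
    """95th percentile of the pooled symmetric surface distances, in mm."""
    if spacing is None:
        spacing = (1.0,) * pred.ndim
    d_pg, d_gp = _surface_distances(pred, gt, spacing)
    return float(np.percentile(np.concatenate([d_pg, d_gp]), 95))


def nsd(pred: np.ndarray, gt: np.ndarray, spacing=None, tau: float = 1.0) -> float:
    """Normalized surface distance: pooled fraction of surface voxels of
    either mask lying within ``tau`` mm of the other mask's surface."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if spacing is None:
        spacing = (1.0,) * pred.ndim
    d_pg, d_gp = _surface_distances(pred, gt, spacing)
    pooled = np.concatenate([d_pg, d_gp])
    return float(np.count_nonzero(pooled <= tau) / pooled.size)


@dataclass
class SplitMetricsRow:
    """One record of the border true-positive decomposition, in percent.

    ``reference_*`` describe the reference border itself (they sum to 100);
    ``tp_*`` describe how much of it the prediction recovered, all relative
    to the total reference border so that
    ``tp_distinct_pct + tp_completed_pct = tp_total_pct`` exactly.
    """

    class_id: int
    reference_distinct_pct: float
    reference_completed_pct: float
    tp_total_pct: float
    tp_distinct_pct: float
    tp_completed_pct: float
    case_id: str = ""


def reference_border_fractions(split: BorderSplit):
    """Percent of the reference border that is distinct vs completed."""
    n = np.count_nonzero(split.border)
    if n == 0:
        raise UndefinedMetricError("reference border is empty")
    d = 100.0 * np.count_nonzero(split.distinct) / n
    return d, 100.0 - d


def tp_decomposition(gt_split: BorderSplit, pred_border: np.ndarray,
                     match_tolerance: int = 1) -> SplitMetricsRow:
    """Decompose prediction border recall over the reference border.

    A reference-border voxel counts as true positive when a predicted
    border voxel exists within ``match_tolerance`` (Chebyshev radius;
    0 demands exact overlap).  Percentages are all relative to the total
    reference border, so the distinct and completed parts add up to the
    total exactly.
    """
    check_same_grid(gt_split.border, pred_border)
    if match_tolerance < 0:
        raise ValueError("match_tolerance must be >= 0")
    n = np.count_nonzero(gt_split.border)
    if n == 0:
        raise UndefinedMetricError("reference border is empty")
    if not pred_border.any():
        logger.warning("empty prediction border; TP decomposition is all zero")
        matched = np.zeros_like(pred_border, dtype=bool)
    elif match_tolerance == 0:
        matched = pred_border.astype(bool)
    else:
        size = 2 * int(match_tolerance) + 1
        matched = ndimage.binary_dilation(
            pred_border, structure=np.ones((size,) * pred_border.ndim, bool))
    tp = gt_split.border & matched
    ref_d, ref_c = reference_border_fractions(gt_split)
    tp_d = 100.0 * np.count_nonzero(tp & gt_split.distinct) / n
    tp_c = 100.0 * np.count_nonzero(tp & gt_split.completed) / n
    return SplitMetricsRow(
        class_id=gt_split.class_id,
        reference_distinct_pct=ref_d,
        reference_completed_pct=ref_c,
        tp_total_pct=tp_d + tp_c,
        tp_distinct_pct=tp_d,
        tp_completed_pct=tp_c,
    )


def aggregate(rows) -> dict:
    """Mean and sample (n-1) standard deviation per numeric column.

    Accepts a list of dataclass rows or of dicts; returns
    ``{column: (mean, sd)}``.  A single row yields sd 0.
    """
    if not rows:
        raise ValueError("aggregate needs at least one row")
    if hasattr(rows[0], "__dataclass_fields__"):
        records = [
            {f.name: getattr(r, f.name) for f in fields(r)} for r in rows
        ]
    else:
        records = list(rows)
    out = {}
    for key in records[0]:
        vals = [r[key] for r in records]
        if not all(isinstance(v, (int, float, np.floating, np.integer))
                   for v in vals):
            continue
        arr = np.asarray(vals, dtype=float)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        out[key] = (float(arr.mean()), sd)
    return out


def compute_class_weights(labels, n_classes: int) -> np.ndarray:
    """Inverse-frequency class weights, normalized to sum to 1.

    Frequencies are pooled over the whole training label set; every class
    in ``range(n_classes)`` must occur at least once.
    """
    counts = np.zeros(n_classes, dtype=np.int64)
    for lab in labels:
        data = lab.data if hasattr(lab, "data") else np.asarray(lab)
        counts += np.bincount(data.ravel(), minlength=n_classes)[:n_classes]
    if (counts == 0).any():
        missing = np.flatnonzero(counts == 0).tolist()
        raise ValueError(f"classes {missing} absent from the pooled label set")
    freq = counts / counts.sum()
    w = 1.0 / freq
    return w / w.sum()
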