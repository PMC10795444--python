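"""Segmentation evaluation: overlap metrics and the Hausdorff distance.

Conventions (the literature rarely states them, so they are fixed here
and documented):

* Metrics are volumetric — slices of a case are stacked and evaluated
  as one 3-D mask pair.
* Both masks empty counts as perfect agreement (all rates 1); exactly
  one empty gives Dice = Jaccard = 0 and the undefined rate 0.
* The Hausdorff distance is the classic symmetric maximum (the
  100th percentile) between boundary voxel sets, with Euclidean
  distances measured in millimetres using the voxel spacing.  It is
  undefined (raises) when either mask is empty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree

__all__ = [
    "MetricsReport",
    "overlap_metrics",
    "hausdorff",
    "boundary_voxels",
    "evaluate_case",
    "batch_report",
    "EmptyMaskError",
]


class EmptyMaskError(ValueError):
    """Raised when a distance metric is requested for an empty mask."""


@dataclass
class MetricsReport:
    dice: float
    jaccard: float
    precision: float
    recall: float
    hausdorff_mm: float | None
    organ: str = ""
    case_id: str = ""


def _validate_pair(pred, ref):
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    return pred.astype(bool), ref.astype(bool)


def overlap_metrics(pred, ref) -> tuple[float, float, float, float]:
    """(Dice, Jaccard, Precision, Recall) between binary masks.

    Dice = 2|A∩B| / (|A|+|B|), Jaccard = |A∩B| / |A∪B|,
    Precision = TP/(TP+FP), Recall = TP/(TP+FN), where A is the
    prediction and B the reference.
    """
    a, b = _validate_pair(pred, ref)
    tp = float(np.count_nonzero(a & b))
    na, nb = float(np.count_nonzero(a)), float(np.count_nonzero(b))
    if na == 0 and nb == 0:
        return 1.0, 1.0, 1.0, 1.0
    dice = 2.0 * tp / (na + nb)
    union = na + nb - tp
    jaccard = tp / union if union else 1.0
    precision = tp / na if na else 0.0
    recall = tp / nb if nb else 0.0
    return dice, jaccard, precision, recall


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Indices (k, ndim) of voxels on the mask boundary.

    A boundary voxel is a foreground voxel lost under one step of
    binary erosion (face connectivity, border treated as background).
    Single-voxel or thin structures are their own boundary.
    """
    mask = np.asarray(mask).astype(bool)
    eroded = binary_erosion(mask, border_value=0)
    return np.argwhere(mask & ~eroded)


def hausdorff(pred, ref, spacing) -> float:
    """Symmetric Hausdorff distance in mm between mask boundaries.

    H(A,B) = max(h(A,B), h(B,A)) with h(A,B) = max_a min_b ||a - b||,
    computed over boundary voxel coordinates scaled by `spacing`
    (one value per array axis, mm).
    """
    a, b = _validate_pair(pred, ref)
    if not a.any() or not b.any():
        raise EmptyMaskError("Hausdorff distance undefined for empty masks")
    spacing = np.asarray(spacing, dtype=np.float64)
    if spacing.shape != (a.ndim,) or (spacing <= 0).any():
        raise ValueError("spacing must give one positive value per axis")
    pa = boundary_voxels(a) * spacing
    pb = boundary_voxels(b) * spacing
    d_ab = cKDTree(pb).query(pa)[0].max()
    d_ba = cKDTree(pa).query(pb)[0].max()
    return float(max(d_ab, d_ba))


def evaluate_case(pred, ref, spacing=None, organ: str = "",
                  case_id: str = "") -> MetricsReport:
    """All five metrics for one mask pair; HD omitted when not computable."""
    dice, jac, prec, rec = overlap_metrics(pred, ref)
    hd = None
    if spacing is not None:
        try:
            hd = hausdorff(pred, ref, spacing)
        except EmptyMaskError:
            hd = None
    return MetricsReport(dice=dice, jaccard=jac, precision=prec,
                         recall=rec, hausdorff_mm=hd, organ=organ,
                         case_id=case_id)


def batch_report(cases, spacing=None, organ: str = "",
                 case_ids=None) -> pd.DataFrame:
    """Per-case metric rows plus mean and SD aggregate rows.

    `cases` is a list of (pred, ref) mask pairs.  Non-computable cells
    (e.g. Hausdorff with an empty mask) are left missing and excluded
    from the aggregates.
    """
    if len(cases) == 0:
        raise ValueError("need at least one case")
    if case_ids is None:
        case_ids = [f"case{i:03d}" for i in range(len(cases))]
    rows = []
    for cid, (pred, ref) in zip(case_ids, cases):
        r = evaluate_case(pred, ref, spacing=spacing, organ=organ,
                          case_id=cid)
        rows.append({"case_id": r.case_id, "organ": organ, "dice": r.dice,
                     "jaccard": r.jaccard, "precision": r.precision,
                     "recall": r.recall, "hausdorff_mm": r.hausdorff_mm})
    df = pd.DataFrame(rows)
    metric_cols = ["dice", "jaccard", "precision", "recall", "hausdorff_mm"]
    mean_row = {"case_id": "mean", "organ": organ,
                **{c: df[c].mean() for c in metric_cols}}
    sd_row = {"case_id": "sd", "organ": organ,
              **{c: df[c].std(ddof=1) if df[c].notna().sum() > 1 else np.nan
                 for c in metric_cols}}
    return pd.concat([df, pd.DataFrame([mean_row, sd_row])],
                     ignore_index=True)
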