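"""Segmentation evaluation metrics.

Validation uses the per-slice (2D) Dice score; testing evaluates each
patient volume in 3D with the Dice score (percent) and the symmetric
Hausdorff distance in voxel units (index space, no physical spacing), i.e.
the worst-case boundary deviation between prediction and ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "EvalRecord", "dice_2d", "dice_3d", "hausdorff_3d", "aggregate",
    "records_to_frame",
]


@dataclass(frozen=True)
class EvalRecord:
    """Per-patient 3D test result under one strategy and target domain."""

    patient_id: str
    strategy: str
    source_domain: str
    target_domain: str
    dice_3d: float
    hausdorff_3d: float
    per_slice_dice: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.dice_3d <= 100.0:
            raise ValueError("dice_3d must lie in [0, 100]")
        if self.hausdorff_3d < 0.0:
            raise ValueError("hausdorff_3d must be non-negative")


def _binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary")
    return arr.astype(bool)


def _dice_percent(pred: np.ndarray, gt: np.ndarray) -> float:
    intersection = np.count_nonzero(pred & gt)
    total = np.count_nonzero(pred) + np.count_nonzero(gt)
    if total == 0:
        return 100.0  # both empty: perfect agreement by convention
    return 100.0 * 2.0 * intersection / total


def dice_2d(pred: np.ndarray, gt: np.ndarray) -> float:
    """Dice overlap of two binary slices, in percent."""
    pred, gt = _binary(pred, "pred"), _binary(gt, "gt")
    if pred.shape != gt.shape or pred.ndim != 2:
        raise ValueError(f"expected equal 2D shapes, got {pred.shape} vs {gt.shape}")
    return _dice_percent(pred, gt)


def dice_3d(pred, gt) -> float:
    """Dice overlap over all voxels of a patient volume, in percent."""
    pred_v = _binary(getattr(pred, "voxels", pred), "pred")
    gt_v = _binary(getattr(gt, "voxels", gt), "gt")
    if pred_v.shape != gt_v.shape or pred_v.ndim != 3:
        raise ValueError(f"expected equal 3D shapes, got {pred_v.shape} vs {gt_v.shape}")
    return _dice_percent(pred_v, gt_v)


def hausdorff_3d(pred, gt) -> float:
    """Symmetric Hausdorff distance between voxel sets, in voxel units.

    ``max(h(P, G), h(G, P))`` with ``h(A, B)`` the maximum over A of the
    Euclidean distance to the nearest voxel of B, computed exactly via
    Euclidean distance transforms.  Conventions for degenerate inputs: both
    sets empty -> 0; exactly one empty -> the image diagonal length (a
    conservative, finite worst case).
    """
    pred_v = _binary(getattr(pred, "voxels", pred), "pred")
    gt_v = _binary(getattr(gt, "voxels", gt), "gt")
    if pred_v.shape != gt_v.shape:
        raise ValueError(f"shape mismatch: {pred_v.shape} vs {gt_v.shape}")
    p_any, g_any = pred_v.any(), gt_v.any()
    if not p_any and not g_any:
        return 0.0
    if not p_any or not g_any:
        return float(np.linalg.norm(pred_v.shape))
    dist_to_gt = ndimage.distance_transform_edt(~gt_v)
    dist_to_pred = ndimage.distance_transform_edt(~pred_v)
    return float(max(dist_to_gt[pred_v].max(), dist_to_pred[gt_v].max()))


def records_to_frame(records: Iterable[EvalRecord]) -> pd.DataFrame:
    rows = [{
        "patient_id": r.patient_id, "strategy": r.strategy,
        "source_domain": r.source_domain, "target_domain": r.target_domain,
        "dice_3d": r.dice_3d, "hausdorff_3d": r.hausdorff_3d,
    } for r in records]
    return pd.DataFrame(rows)


def aggregate(records: Sequence[EvalRecord]) -> pd.DataFrame:
    """Mean and population standard deviation per strategy x target domain.

    One row per (strategy, target_domain) with columns ``dice_mean``,
    ``dice_std``, ``hausdorff_mean``, ``hausdorff_std``, ``n_patients`` —
    the layout of a per-strategy results table.
    """
    frame = records_to_frame(records)
    if frame.empty:
        raise ValueError("no records to aggregate")

    def _pop_std(x):
        return float(np.std(np.asarray(x, dtype=float)))

    grouped = frame.groupby(["strategy", "target_domain"], sort=False)
    out = grouped.agg(
        dice_mean=("dice_3d", "mean"),
        dice_std=("dice_3d", _pop_std),
        hausdorff_mean=("hausdorff_3d", "mean"),
        hausdorff_std=("hausdorff_3d", _pop_std),
        n_patients=("patient_id", "nunique"),
    ).reset_index()
    return out
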