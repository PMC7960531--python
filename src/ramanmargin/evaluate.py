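"""Quantitative evaluation against ground truth.

Delineation accuracy is reported as true-positive, false-negative, and
false-positive areas, each expressed as a percentage of the ground-truth
lesion area (so TP + FN = 100 exactly and FP may exceed 100).  Tracking
accuracy is the per-frame Euclidean tip error in mm over the valid frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .delineate import build_boundary

__all__ = [
    "AreaMetrics",
    "TrackingErrorStats",
    "area_metrics",
    "tracking_error",
    "margin_sweep_report",
]


@dataclass(frozen=True)
class AreaMetrics:
    """TP/FN/FP of a delineated region, as % of ground-truth area and mm²."""

    tp_pct: float
    fn_pct: float
    fp_pct: float
    areas_mm2: dict


@dataclass(frozen=True)
class TrackingErrorStats:
    """Tip-localization error over valid frames (mm)."""

    mean_mm: float
    sd_mm: float
    per_frame_mm: np.ndarray
    n_valid_frames: int


def area_metrics(pred_mask: np.ndarray, truth_mask: np.ndarray, mm_per_px: float) -> AreaMetrics:
    """Compare a delineated mask with the ground-truth lesion mask."""
    pred = np.asarray(pred_mask, dtype=bool)
    truth = np.asarray(truth_mask, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("masks must share one shape")
    n_truth = int(truth.sum())
    if n_truth == 0:
        raise ValueError("ground-truth mask is empty")
    tp = int((pred & truth).sum())
    fn = int((truth & ~pred).sum())
    fp = int((pred & ~truth).sum())
    px_mm2 = mm_per_px ** 2
    return AreaMetrics(
        tp_pct=100.0 * tp / n_truth,
        fn_pct=100.0 * fn / n_truth,
        fp_pct=100.0 * fp / n_truth,
        areas_mm2={"tp": tp * px_mm2, "fn": fn * px_mm2, "fp": fp * px_mm2,
                   "truth": n_truth * px_mm2},
    )


def tracking_error(pose_table: pd.DataFrame, truth_table: pd.DataFrame,
                   mm_per_px_truth: float) -> TrackingErrorStats:
    """Per-frame Euclidean tip error (mm) of a tracked pose table against
    the ground-truth trajectory; invalid frames are excluded and counted."""
    if len(pose_table) != len(truth_table):
        raise ValueError("pose and truth tables must have equal frame counts")
    valid = pose_table["valid"].to_numpy(dtype=bool)
    if not valid.any():
        raise ValueError("no valid frames to evaluate")
    dx = pose_table["tipx"].to_numpy() - truth_table["tipx"].to_numpy()
    dy = pose_table["tipy"].to_numpy() - truth_table["tipy"].to_numpy()
    err_mm = np.hypot(dx, dy)[valid] * mm_per_px_truth
    return TrackingErrorStats(
        mean_mm=float(err_mm.mean()),
        sd_mm=float(err_mm.std(ddof=0)),
        per_frame_mm=err_mm,
        n_valid_frames=int(valid.sum()),
    )


def margin_sweep_report(positives, truth_mask: np.ndarray, margins_mm,
                        mm_per_px: float, tip_diameter_mm: float = 0.0) -> pd.DataFrame:
    """Delineate at each safety margin and tabulate the area metrics."""
    rows = []
    for margin in margins_mm:
        result = build_boundary(positives, margin, mm_per_px, truth_mask.shape,
                                tip_diameter_mm=tip_diameter_mm)
        m = area_metrics(result.mask, truth_mask, mm_per_px)
        rows.append({"margin_mm": float(margin), "tp_pct": m.tp_pct,
                     "fn_pct": m.fn_pct, "fp_pct": m.fp_pct,
                     "tp_mm2": m.areas_mm2["tp"], "fn_mm2": m.areas_mm2["fn"],
                     "fp_mm2": m.areas_mm2["fp"]})
    return pd.DataFrame(rows)
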