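"""Spatial diagnosis accumulation, margin delineation, and overlays.

Positive (diseased) diagnoses recorded at tracked probe-tip locations are
connected into a lesion boundary — the convex hull of the positive points —
which is expanded outward by a clinician-chosen safety margin (in mm,
converted to pixels with the median per-acquisition scale).  Because a
probe tip of finite width senses a disk rather than a point, half the tip
diameter can be added to the buffer radius.  The module also renders the
AR-style overlay (numbered green/red squares plus the boundary polyline)
and provides simple threshold-based delineation of widefield fluorescence
images for comparison with the Raman route.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from PIL import Image, ImageDraw
from shapely.geometry import LineString, MultiPoint, Point
from skimage.filters import threshold_otsu

from .plsda import Diagnosis
from .tracking import ProbePose

__all__ = [
    "DiagnosisRecord",
    "DiagnosisStore",
    "DelineationResult",
    "add_diagnosis",
    "build_boundary",
    "suggest_points",
    "render_overlay",
    "fluorescence_delineation",
]


@dataclass(frozen=True)
class DiagnosisRecord:
    """One spatial diagnosis: acquisition order (1-based, as displayed),
    probe-tip pixel coordinate, class label, positive-class score, binary
    call, and the frame's mm/px scale."""

    index: int
    tip_px: tuple
    label: str
    score: float
    positive: bool
    mm_per_px: float


class DiagnosisStore:
    """Append-only record of spatial diagnoses.

    Delineation is a pure function of the store, so the display can always
    be re-rendered from it — including after frames where the probe was
    occluded and produced no new measurement.
    """

    def __init__(self, records=()) -> None:
        self.records: list[DiagnosisRecord] = list(records)
        for i, r in enumerate(self.records, start=1):
            if r.index != i:
                raise ValueError("record indices must be contiguous from 1")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def positives(self) -> list[DiagnosisRecord]:
        return [r for r in self.records if r.positive]

    @property
    def positive_points(self) -> np.ndarray:
        pts = [r.tip_px for r in self.positives]
        return np.asarray(pts, dtype=float).reshape(-1, 2)

    def median_mm_per_px(self) -> float:
        scales = [r.mm_per_px for r in self.records if np.isfinite(r.mm_per_px)]
        if not scales:
            raise ValueError("store holds no finite mm/px scales")
        return float(np.median(scales))

    def to_csv(self, path) -> None:
        pd.DataFrame([
            {"index": r.index, "tipx": r.tip_px[0], "tipy": r.tip_px[1],
             "label": r.label, "score": r.score, "positive": r.positive,
             "mm_per_px": r.mm_per_px}
            for r in self.records
        ]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DiagnosisStore":
        df = pd.read_csv(path)
        return cls([
            DiagnosisRecord(index=int(row["index"]), tip_px=(row["tipx"], row["tipy"]),
                            label=str(row["label"]), score=float(row["score"]),
                            positive=bool(row["positive"]), mm_per_px=float(row["mm_per_px"]))
            for _, row in df.iterrows()
        ])


def add_diagnosis(store: DiagnosisStore, pose: ProbePose, diag: Diagnosis) -> DiagnosisStore:
    """Append a diagnosis at the current tip location; invalid poses
    (occluded/missed frames) are rejected."""
    if not pose.valid:
        raise ValueError("cannot record a diagnosis for an invalid probe pose")
    store.records.append(DiagnosisRecord(
        index=len(store.records) + 1,
        tip_px=pose.tip_px,
        label=diag.label,
        score=diag.scores.get(diag.label, float("nan")),
        positive=diag.positive,
        mm_per_px=pose.mm_per_px,
    ))
    return store


@dataclass(frozen=True)
class DelineationResult:
    """Delineated lesion: boundary polygon vertices (px), the applied
    safety margin, and the rasterized binary mask at frame size."""

    boundary: np.ndarray
    margin_mm: float
    mask: np.ndarray
    mm_per_px: float


def _positive_geometry(points: np.ndarray, radius_px: float):
    """Hull of the positive points, buffered outward by radius_px."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        return None
    if pts.shape[0] == 1:
        base = Point(pts[0])
    elif pts.shape[0] == 2:
        base = LineString(pts)
    else:
        base = MultiPoint(pts).convex_hull
    if radius_px > 0:
        return base.buffer(radius_px, quad_segs=64)
    return base


def _rasterize(geom, frame_shape) -> np.ndarray:
    """Half-open pixel coverage: pixel (row, col) is inside when its center
    (x=col, y=row) lies inside the polygon."""
    h, w = frame_shape[:2]
    mask = np.zeros((h, w), dtype=bool)
    if geom is None or geom.is_empty or geom.area == 0:
        return mask
    minx, miny, maxx, maxy = geom.bounds
    x0 = max(0, int(np.floor(minx)))
    x1 = min(w - 1, int(np.ceil(maxx)))
    y0 = max(0, int(np.floor(miny)))
    y1 = min(h - 1, int(np.ceil(maxy)))
    if x0 > x1 or y0 > y1:
        return mask
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    inside = shapely.contains_xy(geom, xs.ravel(), ys.ravel()).reshape(xs.shape)
    mask[y0 : y1 + 1, x0 : x1 + 1] = inside
    return mask


def build_boundary(positives, margin_mm: float, mm_per_px: float, frame_shape,
                   tip_diameter_mm: float = 0.0) -> DelineationResult:
    """Connect positive points into a margin-expanded lesion boundary.

    Effective buffer radius = margin_mm + tip_diameter_mm / 2, converted to
    pixels.  0 positives → empty mask; 1 → disk; 2 → capsule; ≥3 → buffered
    convex hull.  The mask is clipped to the frame.
    """
    if mm_per_px <= 0:
        raise ValueError("mm_per_px must be positive")
    if margin_mm < 0:
        raise ValueError("margin_mm must be non-negative")
    radius_px = (margin_mm + tip_diameter_mm / 2.0) / mm_per_px
    geom = _positive_geometry(np.asarray(positives, dtype=float).reshape(-1, 2), radius_px)
    if geom is None:
        boundary = np.empty((0, 2))
        mask = np.zeros(frame_shape[:2], dtype=bool)
    else:
        if geom.geom_type == "Polygon":
            boundary = np.asarray(geom.exterior.coords)
        elif geom.geom_type == "Point":
            boundary = np.asarray([[geom.x, geom.y]])
        else:
            boundary = np.asarray(geom.coords)
        mask = _rasterize(geom, frame_shape)
    return DelineationResult(boundary=boundary, margin_mm=float(margin_mm),
                             mask=mask, mm_per_px=float(mm_per_px))


def suggest_points(store: DiagnosisStore, spacing_mm: float,
                   mm_per_px: float | None = None, margin_mm: float = 0.0,
                   tip_diameter_mm: float = 0.0) -> np.ndarray:
    """Suggest the next measurement locations.

    Candidates sit on the current boundary offset outward by spacing_mm, at
    arc-length intervals of spacing_mm, skipping locations within
    spacing_mm of any existing measurement.  Empty when the store has no
    positives.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing_mm must be positive")
    pts = store.positive_points
    if pts.shape[0] == 0:
        return np.empty((0, 2))
    scale = mm_per_px if mm_per_px is not None else store.median_mm_per_px()
    spacing_px = spacing_mm / scale
    radius_px = (margin_mm + tip_diameter_mm / 2.0) / scale
    base = _positive_geometry(pts, radius_px)
    ring = base.buffer(spacing_px, quad_segs=64).exterior
    n = max(3, int(round(ring.length / spacing_px)))
    candidates = np.asarray([
        ring.interpolate(i * ring.length / n).coords[0] for i in range(n)
    ])
    existing = np.asarray([r.tip_px for r in store.records], dtype=float).reshape(-1, 2)
    dists = np.hypot(
        candidates[:, None, 0] - existing[None, :, 0],
        candidates[:, None, 1] - existing[None, :, 1],
    ).min(axis=1)
    # small tolerance absorbs the polygonal approximation of the buffer arc
    return candidates[dists >= spacing_px * (1.0 - 1e-3)]


_NEG_COLOR = (0, 190, 0)
_POS_COLOR = (220, 30, 30)
_BOUNDARY_COLOR = (220, 30, 30)
_SQUARE_HALF = 6


def render_overlay(frame: np.ndarray, store: DiagnosisStore,
                   result: DelineationResult | None = None) -> np.ndarray:
    """Draw the AR overlay: numbered green (negative) / red (positive)
    squares at the acquisition locations plus the boundary polyline.
    Deterministic given inputs; an empty store returns an unchanged copy."""
    frame = np.asarray(frame)
    if frame.dtype != np.uint8:
        frame = (np.clip(frame, 0, 1) * 255).astype(np.uint8)
    if result is not None and result.mask.shape != frame.shape[:2]:
        raise ValueError("frame size does not match delineation mask")
    img = Image.fromarray(frame.copy())
    draw = ImageDraw.Draw(img)
    if result is not None and result.boundary.shape[0] >= 3:
        draw.line([tuple(p) for p in result.boundary], fill=_BOUNDARY_COLOR, width=2)
    for rec in store.records:
        x, y = rec.tip_px
        color = _POS_COLOR if rec.positive else _NEG_COLOR
        draw.rectangle([x - _SQUARE_HALF, y - _SQUARE_HALF,
                        x + _SQUARE_HALF, y + _SQUARE_HALF],
                       outline=color, fill=color)
        draw.text((x - 3, y - 6), str(rec.index), fill=(255, 255, 255))
    return np.asarray(img)


def fluorescence_delineation(image: np.ndarray, threshold_mode: str = "fixed",
                             threshold_value: float | None = None,
                             largest_component: bool = False) -> np.ndarray:
    """Threshold a single-channel fluorescence image into a lesion mask.

    mode="fixed" uses threshold_value directly; mode="auto" uses Otsu's
    bimodal threshold (an error on a flat image, which has no bimodality).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("fluorescence image must be single-channel")
    if threshold_mode == "fixed":
        if threshold_value is None:
            raise ValueError("fixed mode requires threshold_value")
        thr = float(threshold_value)
    elif threshold_mode == "auto":
        if np.ptp(image) == 0:
            raise ValueError("flat image: automatic threshold undefined")
        thr = float(threshold_otsu(image))
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    mask = image >= thr
    if largest_component and mask.any():
        from skimage.measure import label

        lab = label(mask)
        counts = np.bincount(lab.ravel())
        counts[0] = 0
        mask = lab == int(np.argmax(counts))
    return mask
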