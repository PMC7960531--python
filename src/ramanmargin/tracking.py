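"""Fiducial-marker probe tracking.

The handheld spectroscopic probe carries two colinear colored markers.
Each video frame is segmented in HSV space (hue is treated circularly so
red markers straddling 0° behave correctly), the two marker centroids are
located, and the probe tip is extrapolated ratiometrically from the known
marker separation and tip offset.  Tracking is stateless: every frame is
processed independently, so the tracker recovers immediately after
occlusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv
from skimage.measure import label, regionprops
from skimage.morphology import closing, opening

__all__ = [
    "MarkerSpec",
    "ProbeGeometry",
    "ProbePose",
    "calibrate_hsv",
    "segment_markers",
    "estimate_tip",
    "track_video",
]


@dataclass(frozen=True)
class MarkerSpec:
    """HSV window for one marker: hue center ± tolerance (degrees on the
    hue circle) with minimum saturation and value."""

    name: str
    hue_center: float
    hue_tol: float = 20.0
    sat_min: float = 0.5
    val_min: float = 0.5
    min_area_px: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.hue_center < 360.0:
            raise ValueError("hue_center must lie in [0, 360)")
        if self.hue_tol <= 0:
            raise ValueError("hue_tol must be positive")


@dataclass(frozen=True)
class ProbeGeometry:
    """Physical probe constants (mm): center-to-center marker separation,
    distal-marker-to-tip offset along the probe axis, and tip width."""

    marker_separation_mm: float = 20.0
    tip_offset_mm: float = 30.0
    tip_diameter_mm: float = 2.1

    def __post_init__(self) -> None:
        if min(self.marker_separation_mm, self.tip_offset_mm, self.tip_diameter_mm) <= 0:
            raise ValueError("probe geometry lengths must be positive")


@dataclass(frozen=True)
class ProbePose:
    """Per-frame pose: marker centroids, extrapolated tip, in-plane angle,
    and the frame's mm/px scale.  Pixel coordinates, origin top-left,
    x rightward, y downward."""

    proximal_px: tuple
    distal_px: tuple
    tip_px: tuple
    angle_rad: float
    mm_per_px: float
    valid: bool

    @classmethod
    def invalid(cls) -> "ProbePose":
        nan = (float("nan"), float("nan"))
        return cls(nan, nan, nan, float("nan"), float("nan"), False)


def hue_distance_deg(h1, h2):
    """Shortest distance on the 360° hue circle."""
    d = np.abs(np.asarray(h1) - np.asarray(h2)) % 360.0
    return np.minimum(d, 360.0 - d)


def _as_float_rgb(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] < 3:
        raise ValueError("frame must be an H×W×3 color image")
    if frame.dtype == np.uint8:
        return frame[..., :3] / 255.0
    return frame[..., :3].astype(float)


def calibrate_hsv(frame: np.ndarray, seed_points, names=("proximal", "distal"),
                  window: int = 5, hue_tol: float = 20.0, slack: float = 0.1,
                  min_area_px: int = 10) -> list[MarkerSpec]:
    """Derive marker HSV windows from one seed pixel per marker.

    Statistics come from a (2·window+1)² neighborhood around each seed:
    circular median hue, and 5th-percentile saturation/value minus slack.
    A seed on an unsaturated background, or two seeds whose hue windows
    overlap, is a calibration error.
    """
    hsv = rgb2hsv(_as_float_rgb(frame))
    specs: list[MarkerSpec] = []
    for name, (sx, sy) in zip(names, seed_points):
        x, y = int(round(sx)), int(round(sy))
        y0, y1 = max(0, y - window), min(hsv.shape[0], y + window + 1)
        x0, x1 = max(0, x - window), min(hsv.shape[1], x + window + 1)
        patch = hsv[y0:y1, x0:x1].reshape(-1, 3)
        sat = patch[:, 1]
        if np.median(sat) < 0.25:
            raise ValueError(f"seed for {name!r} lies on a low-saturation region")
        core = patch[sat >= 0.25]
        ang = core[:, 0] * 2.0 * np.pi
        hue = float(np.degrees(np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())) % 360.0)
        specs.append(MarkerSpec(
            name=name,
            hue_center=hue,
            hue_tol=hue_tol,
            sat_min=max(0.05, float(np.percentile(core[:, 1], 5)) - slack),
            val_min=max(0.05, float(np.percentile(core[:, 2], 5)) - slack),
            min_area_px=min_area_px,
        ))
    for i in range(len(specs)):
        for j in range(i + 1, len(specs)):
            if hue_distance_deg(specs[i].hue_center, specs[j].hue_center) <= (
                specs[i].hue_tol + specs[j].hue_tol
            ):
                raise ValueError(
                    f"hue windows of {specs[i].name!r} and {specs[j].name!r} overlap"
                )
    return specs


def segment_markers(frame: np.ndarray, specs) -> dict:
    """Segment each marker; returns {name: (centroid_xy, area) or None}.

    Mask = circular hue distance ≤ tol AND S ≥ sat_min AND V ≥ val_min,
    cleaned with a 3×3 morphological open then close; the largest connected
    component gives the centroid.  Too-small components are misses, not
    errors.
    """
    hsv = rgb2hsv(_as_float_rgb(frame))
    hue_deg = hsv[..., 0] * 360.0
    footprint = np.ones((3, 3), dtype=bool)
    out: dict = {}
    for spec in specs:
        mask = (
            (hue_distance_deg(hue_deg, spec.hue_center) <= spec.hue_tol)
            & (hsv[..., 1] >= spec.sat_min)
            & (hsv[..., 2] >= spec.val_min)
        )
        mask = closing(opening(mask, footprint), footprint)
        lab = label(mask)
        props = regionprops(lab)
        if not props:
            out[spec.name] = None
            continue
        best = max(props, key=lambda p: p.area)
        if best.area < spec.min_area_px:
            out[spec.name] = None
            continue
        cy, cx = best.centroid
        out[spec.name] = ((float(cx), float(cy)), int(best.area))
    return out


def estimate_tip(proximal_px, distal_px, geom: ProbeGeometry) -> ProbePose:
    """Ratiometric tip extrapolation from the two marker centroids.

    The pixel distance between markers fixes this frame's mm/px scale;
    the tip sits tip_offset_mm beyond the distal marker along the
    proximal→distal axis.
    """
    prox = np.asarray(proximal_px, dtype=float)
    dist = np.asarray(distal_px, dtype=float)
    delta = dist - prox
    norm = float(np.hypot(*delta))
    if norm < 1e-9:
        return ProbePose.invalid()
    mm_per_px = geom.marker_separation_mm / norm
    tip = dist + delta * (geom.tip_offset_mm / geom.marker_separation_mm)
    return ProbePose(
        proximal_px=(float(prox[0]), float(prox[1])),
        distal_px=(float(dist[0]), float(dist[1])),
        tip_px=(float(tip[0]), float(tip[1])),
        angle_rad=float(np.arctan2(delta[1], delta[0])),
        mm_per_px=mm_per_px,
        valid=True,
    )


def track_video(frames, specs, geom: ProbeGeometry) -> pd.DataFrame:
    """Track the probe through a frame sequence.

    One output row per frame (frame, valid, mx1, my1, mx2, my2, tipx, tipy,
    angle, mm_per_px); a frame where either marker is missed yields
    valid=False with NaN coordinates — no pose is carried over.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("empty frame sequence")
    if len(specs) != 2:
        raise ValueError("exactly two marker specs (proximal, distal) required")
    rows = []
    for i, frame in enumerate(frames):
        found = segment_markers(frame, specs)
        prox_hit = found.get(specs[0].name)
        dist_hit = found.get(specs[1].name)
        if prox_hit is None or dist_hit is None:
            pose = ProbePose.invalid()
        else:
            pose = estimate_tip(prox_hit[0], dist_hit[0], geom)
        rows.append({
            "frame": i, "valid": pose.valid,
            "mx1": pose.proximal_px[0], "my1": pose.proximal_px[1],
            "mx2": pose.distal_px[0], "my2": pose.distal_px[1],
            "tipx": pose.tip_px[0], "tipy": pose.tip_px[1],
            "angle": pose.angle_rad, "mm_per_px": pose.mm_per_px,
        })
    return pd.DataFrame(rows)
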