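"""File-format plumbing: PNG frame sequences, mask images, YAML configs."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .tracking import MarkerSpec, ProbeGeometry

__all__ = [
    "write_frames",
    "read_frames",
    "write_mask",
    "read_mask",
    "save_calibration",
    "load_calibration",
]


def write_frames(directory, frames) -> list[Path]:
    """Write frames as a zero-padded PNG sequence (frame_0001.png …)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames, start=1):
        path = directory / f"frame_{i:04d}.png"
        iio.imwrite(path, np.asarray(frame))
        paths.append(path)
    return paths


def read_frames(directory) -> list[np.ndarray]:
    paths = sorted(Path(directory).glob("frame_*.png"))
    if not paths:
        raise FileNotFoundError(f"no frame_*.png files in {directory}")
    return [iio.imread(p) for p in paths]


def write_mask(path, mask: np.ndarray) -> None:
    """Binary mask as an 8-bit 0/255 PNG."""
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    return np.asarray(iio.imread(path)) > 127


def save_calibration(path, specs, geom: ProbeGeometry) -> None:
    payload = {
        "markers": [
            {"name": s.name, "hue_center": s.hue_center, "hue_tol": s.hue_tol,
             "sat_min": s.sat_min, "val_min": s.val_min, "min_area_px": s.min_area_px}
            for s in specs
        ],
        "geometry": {
            "marker_separation_mm": geom.marker_separation_mm,
            "tip_offset_mm": geom.tip_offset_mm,
            "tip_diameter_mm": geom.tip_diameter_mm,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh)


def load_calibration(path) -> tuple[list[MarkerSpec], ProbeGeometry]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    specs = [MarkerSpec(**m) for m in payload["markers"]]
    geom = ProbeGeometry(**payload["geometry"])
    return specs, geom
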