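"""Synthetic inputs with exact ground truth.

Stands in for the tissue specimens, optical phantoms, and surgical video of
the real system: Raman-like spectra built from Gaussian peaks on a smooth
background (plus a broad fluorescence background scaling with a PPIX-analog
concentration), 2D scenes with a known lesion mask, probe-motion video with
colored fiducial markers and a known tip trajectory, and fluorescence
images attenuated by an occluding layer.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.color import hsv2rgb

from .preprocess import RamanSpectrum

__all__ = [
    "SpectrumGenSpec",
    "SceneSpec",
    "VideoGenSpec",
    "fluorescence_template",
    "generate_spectrum",
    "generate_class_spectra",
    "generate_probe_video",
    "generate_fluorescence_image",
    "muscle_spec",
    "fat_spec",
    "phantom_spec",
    "default_scene",
    "composite_phantom_scene",
    "smooth_trajectory",
    "default_video_spec",
]

# Broad fluorescence background: single Gaussian centered mid-axis,
# sigma 400 cm⁻¹ — a qualitative stand-in for the smooth PPIX-driven
# background, not a physical emission model.
FLUOR_SIGMA = 400.0


@dataclass(frozen=True)
class SpectrumGenSpec:
    """Recipe for one spectral class: Gaussian peaks + polynomial baseline
    + concentration-scaled fluorescence background + Gaussian noise.

    ``baseline_coeffs`` are ascending-order polynomial coefficients
    evaluated on the normalized axis coordinate u = (w − start)/(end − start).
    """

    class_name: str
    peak_centers: tuple = ()
    peak_heights: tuple = ()
    peak_widths: tuple = ()
    baseline_coeffs: tuple = (0.0,)
    fluor_amplitude: float = 0.0
    noise_sd: float = 0.0
    axis_start: float = 400.0
    axis_end: float = 2000.0
    axis_step: float = 2.0

    def __post_init__(self) -> None:
        if not (len(self.peak_centers) == len(self.peak_heights) == len(self.peak_widths)):
            raise ValueError("peak_centers, peak_heights, peak_widths must have equal length")
        if self.axis_start >= self.axis_end:
            raise ValueError("axis_start must be < axis_end")
        if self.fluor_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("fluor_amplitude and noise_sd must be non-negative")
        if any(h < 0 for h in self.peak_heights) or any(w <= 0 for w in self.peak_widths):
            raise ValueError("peak heights must be >= 0 and widths > 0")

    @property
    def axis(self) -> np.ndarray:
        return np.arange(self.axis_start, self.axis_end + self.axis_step / 2, self.axis_step)


def fluorescence_template(wavenumbers: np.ndarray, axis_start: float, axis_end: float) -> np.ndarray:
    """Unit-amplitude broad background template (Gaussian, mid-axis center)."""
    center = 0.5 * (axis_start + axis_end)
    return np.exp(-0.5 * ((np.asarray(wavenumbers, float) - center) / FLUOR_SIGMA) ** 2)


def generate_spectrum(spec: SpectrumGenSpec, seed: int) -> RamanSpectrum:
    """Render one noisy spectrum from a class recipe. Deterministic per (spec, seed)."""
    w = spec.axis
    u = (w - spec.axis_start) / (spec.axis_end - spec.axis_start)
    y = np.polynomial.polynomial.polyval(u, np.asarray(spec.baseline_coeffs, float))
    y = np.broadcast_to(y, w.shape).astype(float).copy()
    for c, h, s in zip(spec.peak_centers, spec.peak_heights, spec.peak_widths):
        y += h * np.exp(-0.5 * ((w - c) / s) ** 2)
    y += spec.fluor_amplitude * fluorescence_template(w, spec.axis_start, spec.axis_end)
    if spec.noise_sd > 0:
        y += np.random.default_rng(seed).normal(0.0, spec.noise_sd, size=w.size)
    return RamanSpectrum(w, y, meta={"class": spec.class_name, "seed": seed})


def generate_class_spectra(spec: SpectrumGenSpec, n: int, seed: int) -> list[RamanSpectrum]:
    """n replicate acquisitions of one class, with independent noise draws."""
    seq = np.random.SeedSequence([int(seed), zlib.crc32(spec.class_name.encode()) % (2**31)])
    child_seeds = seq.generate_state(n) % (2**31)
    return [generate_spectrum(spec, int(s)) for s in child_seeds]


# ---------------------------------------------------------------------------
# Spectral class recipes used throughout the examples and evaluation runs.
# Peak positions loosely follow well-known tissue Raman bands (1003
# phenylalanine, 1450 CH₂ deformation, 1655 amide I for muscle; 1078/1300/
# 1440/1745 lipid bands for fat); the phantom analog uses a disjoint set.


def muscle_spec(noise_sd: float = 0.05) -> SpectrumGenSpec:
    return SpectrumGenSpec(
        class_name="muscle",
        peak_centers=(855.0, 936.0, 1003.0, 1250.0, 1450.0, 1655.0),
        peak_heights=(4.0, 4.5, 8.0, 5.0, 7.0, 9.0),
        peak_widths=(12.0, 12.0, 8.0, 18.0, 14.0, 16.0),
        baseline_coeffs=(1.0, 0.8, -0.5),
        noise_sd=noise_sd,
    )


def fat_spec(noise_sd: float = 0.05) -> SpectrumGenSpec:
    return SpectrumGenSpec(
        class_name="fat",
        peak_centers=(1078.0, 1300.0, 1440.0, 1745.0),
        peak_heights=(5.0, 8.0, 10.0, 6.0),
        peak_widths=(14.0, 12.0, 12.0, 10.0),
        baseline_coeffs=(0.8, 0.5, -0.2),
        noise_sd=noise_sd,
    )


def phantom_spec(ppix_um: float = 0.0, noise_sd: float = 0.05) -> SpectrumGenSpec:
    """Optical-tissue-phantom analog; fluorescence background scales with
    the PPIX-analog concentration in µM (0, 2, 4, or 20)."""
    return SpectrumGenSpec(
        class_name=f"phantom_{ppix_um:g}uM",
        peak_centers=(718.0, 760.0, 1127.0, 1340.0, 1585.0),
        peak_heights=(5.0, 4.0, 6.0, 5.5, 7.0),
        peak_widths=(10.0, 10.0, 14.0, 16.0, 12.0),
        baseline_coeffs=(0.6, 0.4, 0.0),
        fluor_amplitude=float(ppix_um),
        noise_sd=noise_sd,
    )


# ---------------------------------------------------------------------------
# Scenes and video


@dataclass(frozen=True)
class SceneSpec:
    """A 2D phantom scene: ground-truth lesion mask, PPIX-analog
    concentration map (µM), and occluding-layer thickness map (mm)."""

    width_px: int
    height_px: int
    lesion_mask: np.ndarray
    mm_per_px: float = 0.5
    concentration_map: np.ndarray | None = None
    occlusion_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        shape = (self.height_px, self.width_px)
        mask = np.asarray(self.lesion_mask, dtype=bool)
        if mask.shape != shape:
            raise ValueError(f"lesion_mask shape {mask.shape} != scene shape {shape}")
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        conc = self.concentration_map
        conc = np.zeros(shape) if conc is None else np.asarray(conc, dtype=float)
        occ = self.occlusion_map
        occ = np.zeros(shape) if occ is None else np.asarray(occ, dtype=float)
        if conc.shape != shape or occ.shape != shape:
            raise ValueError("concentration/occlusion maps must share the scene shape")
        if np.any(conc < 0):
            raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "lesion_mask", mask)
        object.__setattr__(self, "concentration_map", conc)
        object.__setattr__(self, "occlusion_map", occ)


@dataclass(frozen=True)
class VideoGenSpec:
    """Probe-motion video recipe: two colored fiducial markers (hues in
    degrees), their geometry in mm, and a ground-truth tip trajectory
    (per-frame (x, y, angle_rad))."""

    n_frames: int
    marker_colors: tuple = (120.0, 240.0)
    marker_radius_px: float = 8.0
    marker_separation_mm: float = 20.0
    tip_offset_mm: float = 30.0
    trajectory: tuple = ()
    occluded_frames: frozenset = field(default_factory=frozenset)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")
        if len(self.trajectory) != self.n_frames:
            raise ValueError("trajectory length must equal n_frames")
        if self.marker_separation_mm <= 0 or self.tip_offset_mm < 0:
            raise ValueError("marker_separation_mm > 0 and tip_offset_mm >= 0 required")
        h1, h2 = self.marker_colors
        if (h1 - h2) % 360.0 == 0.0:
            raise ValueError("marker colors must have distinct hues")
        object.__setattr__(self, "occluded_frames", frozenset(self.occluded_frames))
        object.__setattr__(self, "trajectory", tuple(tuple(t) for t in self.trajectory))


def smooth_trajectory(
    n_frames: int,
    width_px: int = 640,
    height_px: int = 480,
    margin_px: float = 150.0,
) -> tuple:
    """Smooth Lissajous-style tip path with slowly varying orientation,
    kept far enough inside the frame for the trailing markers to stay visible."""
    t = np.linspace(0.0, 1.0, n_frames)
    cx, cy = width_px / 2.0, height_px / 2.0
    ax = max(10.0, width_px / 2.0 - margin_px)
    ay = max(10.0, height_px / 2.0 - margin_px)
    x = cx + ax * np.sin(2.0 * np.pi * 1.0 * t)
    y = cy + ay * np.sin(2.0 * np.pi * 2.0 * t + 0.7)
    angle = 0.4 * np.sin(2.0 * np.pi * t) + 0.2
    return tuple(zip(x, y, angle))


def default_video_spec(n_frames: int = 180, width_px: int = 640, height_px: int = 480,
                       occluded_frames=(), seed: int = 0) -> VideoGenSpec:
    return VideoGenSpec(
        n_frames=n_frames,
        trajectory=smooth_trajectory(n_frames, width_px, height_px),
        occluded_frames=frozenset(occluded_frames),
        seed=seed,
    )


def _elliptical_mask(shape, center, radii, angle_rad=0.0) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dx, dy = xx - center[0], yy - center[1]
    ca, sa = np.cos(angle_rad), np.sin(angle_rad)
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    return (u / radii[0]) ** 2 + (v / radii[1]) ** 2 <= 1.0


def default_scene(width_px: int = 640, height_px: int = 480, mm_per_px: float = 0.5) -> SceneSpec:
    """Single elliptical lesion in the middle of the field of view."""
    mask = _elliptical_mask((height_px, width_px), (width_px / 2, height_px / 2),
                            (110.0, 75.0), angle_rad=0.3)
    return SceneSpec(width_px, height_px, mask, mm_per_px=mm_per_px)


def composite_phantom_scene(width_px: int = 640, height_px: int = 480,
                            mm_per_px: float = 0.5,
                            conc_high_um: float = 4.0, conc_low_um: float = 2.0,
                            occlusion_mm: float = 1.0) -> SceneSpec:
    """Composite phantom: one region at a higher PPIX-analog concentration
    and an adjacent lower-concentration region hidden under a thin
    (~1 mm) non-fluorescent layer. The lesion ground truth is their union."""
    shape = (height_px, width_px)
    high = _elliptical_mask(shape, (width_px * 0.40, height_px / 2), (80.0, 70.0))
    low = _elliptical_mask(shape, (width_px * 0.62, height_px / 2), (80.0, 70.0)) & ~high
    conc = np.zeros(shape)
    conc[high] = conc_high_um
    conc[low] = conc_low_um
    occ = np.zeros(shape)
    occ[low] = occlusion_mm
    return SceneSpec(width_px, height_px, high | low, mm_per_px=mm_per_px,
                     concentration_map=conc, occlusion_map=occ)


def _marker_rgb(hue_deg: float) -> np.ndarray:
    return hsv2rgb(np.array([[[(hue_deg % 360.0) / 360.0, 1.0, 1.0]]]))[0, 0]


def render_scene_background(scene: SceneSpec) -> np.ndarray:
    """Low-saturation gray scene with the lesion slightly darker — float RGB."""
    base = np.full((scene.height_px, scene.width_px, 3), 0.72)
    base[scene.lesion_mask] = (0.58, 0.56, 0.55)
    return base


def _paint_disk(img: np.ndarray, center_xy, radius: float, rgb: np.ndarray) -> None:
    """Anti-aliased filled disk blended over img in place."""
    cx, cy = center_xy
    x0 = max(0, int(np.floor(cx - radius - 2)))
    x1 = min(img.shape[1], int(np.ceil(cx + radius + 2)) + 1)
    y0 = max(0, int(np.floor(cy - radius - 2)))
    y1 = min(img.shape[0], int(np.ceil(cy + radius + 2)) + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(xx - cx, yy - cy)
    alpha = np.clip(radius + 0.5 - dist, 0.0, 1.0)[..., None]
    img[y0:y1, x0:x1] = (1.0 - alpha) * img[y0:y1, x0:x1] + alpha * rgb


def marker_positions(tip_xy, angle_rad: float, geom_sep_mm: float, tip_offset_mm: float,
                     mm_per_px: float) -> tuple:
    """Invert the ratiometric tip formula: place (proximal, distal) marker
    centers so that exact centroids reproduce the ground-truth tip."""
    u = np.array([np.cos(angle_rad), np.sin(angle_rad)])
    tip = np.asarray(tip_xy, dtype=float)
    distal = tip - u * (tip_offset_mm / mm_per_px)
    proximal = distal - u * (geom_sep_mm / mm_per_px)
    return proximal, distal


def generate_probe_video(scene: SceneSpec, video: VideoGenSpec) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Render the frame sequence and the exact ground-truth table.

    Returns (frames, truth) where frames are uint8 RGB arrays and truth has
    columns frame, mx1, my1, mx2, my2, tipx, tipy, angle, occluded —
    (mx1, my1) the proximal marker, (mx2, my2) the distal one.
    """
    background = render_scene_background(scene)
    rgb_prox = _marker_rgb(video.marker_colors[0])
    rgb_dist = _marker_rgb(video.marker_colors[1])
    frames: list[np.ndarray] = []
    rows = []
    for i, (tx, ty, ang) in enumerate(video.trajectory):
        frame = background.copy()
        prox, dist = marker_positions((tx, ty), ang, video.marker_separation_mm,
                                      video.tip_offset_mm, scene.mm_per_px)
        occluded = i in video.occluded_frames
        if not occluded:
            _paint_disk(frame, prox, video.marker_radius_px, rgb_prox)
            _paint_disk(frame, dist, video.marker_radius_px, rgb_dist)
        frames.append((np.clip(frame, 0, 1) * 255).round().astype(np.uint8))
        rows.append({"frame": i, "mx1": prox[0], "my1": prox[1],
                     "mx2": dist[0], "my2": dist[1],
                     "tipx": float(tx), "tipy": float(ty), "angle": float(ang),
                     "occluded": occluded})
    return frames, pd.DataFrame(rows)


def generate_fluorescence_image(scene: SceneSpec, gain: float = 10.0,
                                noise_sd: float = 0.0,
                                attenuation_per_mm: float = 3.0,
                                seed: int = 0) -> np.ndarray:
    """Widefield fluorescence image of the scene.

    intensity = gain × concentration × exp(−attenuation_per_mm × occlusion)
    + Gaussian noise; zero concentration gives a noise-only background.
    """
    if gain <= 0:
        raise ValueError("gain must be positive")
    if attenuation_per_mm < 0:
        raise ValueError("attenuation_per_mm must be non-negative")
    img = gain * scene.concentration_map * np.exp(-attenuation_per_mm * scene.occlusion_map)
    if noise_sd > 0:
        img = img + np.random.default_rng(seed).normal(0.0, noise_sd, size=img.shape)
    return img
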