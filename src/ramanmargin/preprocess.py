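"""Raman spectral preprocessing chain.

Every spectrum entering the diagnostic model passes through the same fixed
sequence: crop to the fingerprint region (600–1800 cm⁻¹), fluorescence
background subtraction with an asymmetric Whittaker smoother (λ = 100,000),
normalization to the area under the curve, and Savitzky-Golay filtering
(first order, frame width 7).

The Whittaker baseline is the asymmetric penalized-least-squares estimator:
it minimizes ``Σ wᵢ (yᵢ − zᵢ)² + λ Σ (Δᵈ z)²`` where the weights are
re-estimated each round as ``p`` for points above the baseline and ``1 − p``
below, driving the solution toward the lower envelope of the spectrum (the
smooth fluorescence background under the sharp Raman peaks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve
from scipy.signal import savgol_filter

__all__ = [
    "RamanSpectrum",
    "PreprocessConfig",
    "crop_spectrum",
    "whittaker_background",
    "subtract_background",
    "normalize",
    "savitzky_golay",
    "preprocess",
]


@dataclass(frozen=True)
class RamanSpectrum:
    """One Raman acquisition: a strictly increasing wavenumber axis (cm⁻¹)
    and the matching intensity vector (arbitrary counts)."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if w.ndim != 1 or y.ndim != 1 or w.size != y.size:
            raise ValueError("wavenumbers and intensities must be equal-length 1-D vectors")
        if w.size < 2:
            raise ValueError("spectrum needs at least two points")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", y)

    def __len__(self) -> int:
        return self.wavenumbers.size

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"wavenumber": self.wavenumbers, "intensity": self.intensities}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **meta) -> "RamanSpectrum":
        df = pd.read_csv(path)
        return cls(df["wavenumber"].to_numpy(), df["intensity"].to_numpy(), meta=dict(meta))


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the fixed preprocessing chain.

    ``whittaker_lambda`` is the smoothness penalty (larger → stiffer
    baseline); ``whittaker_p`` the asymmetry weight given to points above
    the running baseline (small → baseline hugs the lower envelope).
    """

    crop_low: float = 600.0
    crop_high: float = 1800.0
    whittaker_lambda: float = 1e5
    whittaker_p: float = 0.01
    whittaker_iters: int = 10
    whittaker_diff_order: int = 2
    norm_mode: str = "area"
    sg_order: int = 1
    sg_frame: int = 7

    def __post_init__(self) -> None:
        if self.crop_low >= self.crop_high:
            raise ValueError("crop_low must be < crop_high")
        if not 0.0 < self.whittaker_p < 1.0:
            raise ValueError("whittaker_p must lie in (0, 1)")
        if self.sg_frame % 2 == 0 or self.sg_frame <= self.sg_order:
            raise ValueError("sg_frame must be odd and greater than sg_order")
        if self.norm_mode not in ("area", "max", "vector"):
            raise ValueError(f"unknown norm_mode {self.norm_mode!r}")


def crop_spectrum(s: RamanSpectrum, low: float, high: float) -> RamanSpectrum:
    """Retain exactly the points with ``low <= wavenumber <= high``."""
    keep = (s.wavenumbers >= low) & (s.wavenumbers <= high)
    if not np.any(keep):
        raise ValueError(
            f"crop range [{low}, {high}] does not overlap axis "
            f"[{s.wavenumbers[0]}, {s.wavenumbers[-1]}]"
        )
    return RamanSpectrum(s.wavenumbers[keep], s.intensities[keep], meta=dict(s.meta))


def whittaker_background(
    y: np.ndarray,
    lam: float = 1e5,
    p: float = 0.01,
    iters: int = 10,
    diff_order: int = 2,
) -> np.ndarray:
    """Asymmetric Whittaker (penalized least squares) baseline estimate.

    Solves the sparse banded system ``(W + λ DᵀD) z = W y`` with ``D`` the
    order-``diff_order`` difference matrix, re-estimating the asymmetric
    weights for ``iters`` rounds.  O(n) in spectrum length.
    """
    y = np.asarray(y, dtype=float)
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    n = y.size
    if n < diff_order + 2:
        raise ValueError("input too short for requested difference order")
    D = _diff_matrix(n, diff_order)
    penalty = lam * (D.T @ D)
    w = np.ones(n)
    z = y.copy()
    for _ in range(iters):
        W = sp.diags_array(w, format="csc")
        z = spsolve((W + penalty).tocsc(), w * y)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def _diff_matrix(n: int, order: int) -> sp.csc_array:
    D = sp.eye_array(n, format="csc")
    for _ in range(order):
        m = D.shape[0]
        D = sp.diags_array([-np.ones(m - 1), np.ones(m - 1)], offsets=[0, 1],
                           shape=(m - 1, m), format="csc") @ D
    return sp.csc_array(D)


def subtract_background(s: RamanSpectrum, config: PreprocessConfig) -> RamanSpectrum:
    baseline = whittaker_background(
        s.intensities,
        lam=config.whittaker_lambda,
        p=config.whittaker_p,
        iters=config.whittaker_iters,
        diff_order=config.whittaker_diff_order,
    )
    return RamanSpectrum(s.wavenumbers, s.intensities - baseline, meta=dict(s.meta))


def normalize(s: RamanSpectrum, mode: str = "area") -> RamanSpectrum:
    """Scale intensities so the chosen norm equals one.

    ``area`` divides by the trapezoidal integral over the wavenumber axis,
    ``max`` by the maximum intensity, ``vector`` by the Euclidean norm.
    Positive rescalings of the input map to the same output.
    """
    y = s.intensities
    if mode == "area":
        denom = float(np.trapezoid(y, s.wavenumbers))
    elif mode == "max":
        denom = float(np.max(y))
    elif mode == "vector":
        denom = float(np.linalg.norm(y))
    else:
        raise ValueError(f"unknown norm mode {mode!r}")
    if denom <= 0:
        raise ValueError("cannot normalize: non-positive norm")
    return RamanSpectrum(s.wavenumbers, y / denom, meta=dict(s.meta))


def savitzky_golay(y: np.ndarray, order: int = 1, frame: int = 7) -> np.ndarray:
    """Savitzky-Golay smoothing with mirror padding at the edges."""
    y = np.asarray(y, dtype=float)
    if frame % 2 == 0:
        raise ValueError("frame width must be odd")
    if frame <= order:
        raise ValueError("frame width must exceed polynomial order")
    if y.size < frame:
        raise ValueError("input shorter than frame width")
    return savgol_filter(y, window_length=frame, polyorder=order, mode="mirror")


def preprocess(s: RamanSpectrum, config: PreprocessConfig | None = None) -> RamanSpectrum:
    """Full chain in the fixed order: crop → background subtract →
    normalize → Savitzky-Golay filter."""
    cfg = config or PreprocessConfig()
    s = crop_spectrum(s, cfg.crop_low, cfg.crop_high)
    s = subtract_background(s, cfg)
    s = normalize(s, cfg.norm_mode)
    smoothed = savitzky_golay(s.intensities, order=cfg.sg_order, frame=cfg.sg_frame)
    return RamanSpectrum(s.wavenumbers, smoothed, meta=dict(s.meta))
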