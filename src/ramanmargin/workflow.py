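"""End-to-end desk-scale experiments.

Wires the generators, preprocessing, PLS-DA, tracking, and delineation
modules into the workflows the system is used for: train a diagnostic
model on labelled spectra, walk a measurement grid over a synthetic scene
acquiring and diagnosing spectra at each probe position, delineate the
lesion at a sweep of safety margins, and compare against fluorescence
thresholding.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .delineate import DiagnosisRecord, DiagnosisStore, build_boundary, fluorescence_delineation
from .evaluate import area_metrics, margin_sweep_report
from .plsda import PLSDAModel, SpectralDataset, fit_plsda, predict, venetian_blinds_cv
from .preprocess import PreprocessConfig, preprocess
from .synthetic import (
    SceneSpec,
    SpectrumGenSpec,
    generate_class_spectra,
    generate_fluorescence_image,
    generate_spectrum,
    muscle_spec,
    phantom_spec,
)

__all__ = [
    "preprocess_dataset",
    "train_two_class_model",
    "sample_measurement_points",
    "run_margin_experiment",
    "compare_raman_vs_fluorescence",
]


def preprocess_dataset(spectra, labels, config: PreprocessConfig | None = None) -> SpectralDataset:
    """Apply the full preprocessing chain to each spectrum and stack them."""
    cfg = config or PreprocessConfig()
    processed = [preprocess(s, cfg) for s in spectra]
    return SpectralDataset.from_spectra(processed, labels)


def train_two_class_model(
    positive_spec: SpectrumGenSpec,
    negative_spec: SpectrumGenSpec,
    n_per_class: int = 25,
    seed: int = 0,
    n_components: int = 2,
    config: PreprocessConfig | None = None,
) -> tuple[PLSDAModel, SpectralDataset, float]:
    """Generate, preprocess, fit, and cross-validate a two-class PLS-DA
    model; returns (model, preprocessed dataset, CV accuracy fraction)."""
    spectra = generate_class_spectra(positive_spec, n_per_class, seed)
    spectra += generate_class_spectra(negative_spec, n_per_class, seed + 1)
    labels = [positive_spec.class_name] * n_per_class + [negative_spec.class_name] * n_per_class
    data = preprocess_dataset(spectra, labels, config)
    model = fit_plsda(data, n_components=n_components,
                      positive_class=positive_spec.class_name)
    cv = venetian_blinds_cv(data, n_components=n_components, n_splits=10)
    return model, data, cv.overall_accuracy


def sample_measurement_points(scene: SceneSpec, spacing_mm: float = 10.0,
                              pad_mm: float = 10.0) -> np.ndarray:
    """Regular measurement grid covering the lesion plus a pad, clipped to
    the frame — the suggested-acquisition pattern of a careful operator."""
    rows, cols = np.nonzero(scene.lesion_mask)
    if rows.size == 0:
        raise ValueError("scene has an empty lesion mask")
    step = max(1, int(round(spacing_mm / scene.mm_per_px)))
    pad = int(round(pad_mm / scene.mm_per_px))
    x0, x1 = max(0, cols.min() - pad), min(scene.width_px - 1, cols.max() + pad)
    y0, y1 = max(0, rows.min() - pad), min(scene.height_px - 1, rows.max() + pad)
    xs = np.arange(x0, x1 + 1, step)
    ys = np.arange(y0, y1 + 1, step)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()]).astype(float)


def run_margin_experiment(
    scene: SceneSpec,
    model: PLSDAModel,
    lesion_spec: SpectrumGenSpec,
    normal_spec: SpectrumGenSpec,
    seed: int = 0,
    spacing_mm: float = 10.0,
    margins_mm=(0.0, 1.5, 3.0),
    tip_diameter_mm: float = 2.1,
    config: PreprocessConfig | None = None,
) -> dict:
    """Acquire a diagnosis at every grid point and delineate the lesion.

    At a point inside the ground-truth lesion the probe sees a
    lesion-class spectrum (with the local PPIX-analog fluorescence
    amplitude), elsewhere a normal-class spectrum; each spectrum is
    preprocessed and diagnosed with the given model.  Returns the
    diagnosis store, the per-margin area-metrics table, and the margin
    masks.
    """
    cfg = config or PreprocessConfig()
    points = sample_measurement_points(scene, spacing_mm=spacing_mm)
    rng_seeds = np.random.SeedSequence(seed).generate_state(len(points)) % (2**31)
    store = DiagnosisStore()
    for k, ((x, y), s) in enumerate(zip(points, rng_seeds), start=1):
        in_lesion = bool(scene.lesion_mask[int(y), int(x)])
        if in_lesion:
            local_conc = float(scene.concentration_map[int(y), int(x)])
            spec = _with_fluor(lesion_spec, local_conc)
        else:
            spec = normal_spec
        spectrum = generate_spectrum(spec, int(s))
        diag = predict(model, preprocess(spectrum, cfg))
        store.records.append(DiagnosisRecord(
            index=k, tip_px=(float(x), float(y)), label=diag.label,
            score=diag.scores[model.positive_class], positive=diag.positive,
            mm_per_px=scene.mm_per_px,
        ))
    sweep = margin_sweep_report(store.positive_points, scene.lesion_mask,
                                margins_mm, scene.mm_per_px,
                                tip_diameter_mm=tip_diameter_mm)
    masks = {
        float(m): build_boundary(store.positive_points, m, scene.mm_per_px,
                                 scene.lesion_mask.shape,
                                 tip_diameter_mm=tip_diameter_mm).mask
        for m in margins_mm
    }
    return {"store": store, "sweep": sweep, "masks": masks, "points": points}


def _with_fluor(spec: SpectrumGenSpec, fluor_amplitude: float) -> SpectrumGenSpec:
    from dataclasses import replace

    return replace(spec, fluor_amplitude=float(fluor_amplitude))


def compare_raman_vs_fluorescence(
    scene: SceneSpec,
    seed: int = 0,
    margin_mm: float = 3.5,
    spacing_mm: float = 10.0,
    fluor_gain: float = 10.0,
    fluor_noise_sd: float = 1.0,
    attenuation_per_mm: float = 3.0,
    fluor_threshold: float = 8.0,
    n_train: int = 25,
) -> dict:
    """Head-to-head delineation of one scene by the Raman probe-tracking
    route and by widefield fluorescence thresholding.

    A muscle-vs-phantom PLS-DA model is trained fresh (seeded), the
    measurement grid is diagnosed and delineated at the given safety
    margin, and the fluorescence image of the same scene is thresholded at
    a fixed intensity; both masks are scored against the ground truth.
    """
    model, _, cv_acc = train_two_class_model(
        phantom_spec(0.0), muscle_spec(), n_per_class=n_train, seed=seed + 1000)
    raman = run_margin_experiment(
        scene, model, lesion_spec=phantom_spec(0.0), normal_spec=muscle_spec(),
        seed=seed, spacing_mm=spacing_mm, margins_mm=(margin_mm,))
    fluor_img = generate_fluorescence_image(
        scene, gain=fluor_gain, noise_sd=fluor_noise_sd,
        attenuation_per_mm=attenuation_per_mm, seed=seed + 2000)
    fluor_mask = fluorescence_delineation(fluor_img, "fixed", fluor_threshold)
    raman_metrics = area_metrics(raman["masks"][float(margin_mm)],
                                 scene.lesion_mask, scene.mm_per_px)
    fluor_metrics = area_metrics(fluor_mask, scene.lesion_mask, scene.mm_per_px)
    return {
        "model_cv_accuracy": cv_acc,
        "raman": raman_metrics,
        "fluorescence": fluor_metrics,
        "raman_mask": raman["masks"][float(margin_mm)],
        "fluorescence_mask": fluor_mask,
        "fluorescence_image": fluor_img,
        "store": raman["store"],
    }
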