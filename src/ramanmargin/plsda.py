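"""PLS-DA classification of preprocessed Raman spectra.

PLS-DA regresses one-hot class indicators on the spectra via PLS2 (latent
variables are successive directions maximizing X–Y covariance); a spectrum
is assigned the class with the largest continuous response, and an
adjustable threshold on the designated positive class drives the binary
positive/negative display used for margin work.  Model validation uses
Venetian-blinds cross-validation: sample i belongs to fold i mod n_splits
in dataset order.  PCA (mean-centered) is provided for unsupervised
phantom discrimination.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA

from .preprocess import RamanSpectrum

__all__ = [
    "SpectralDataset",
    "PLSDAModel",
    "Diagnosis",
    "CVResult",
    "fit_plsda",
    "predict",
    "venetian_blinds_cv",
    "pca_scores",
]


@dataclass(frozen=True)
class SpectralDataset:
    """n_samples × n_features intensity matrix with per-sample class labels
    and the shared wavenumber axis."""

    matrix: np.ndarray
    labels: tuple
    axis: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.matrix, dtype=float)
        axis = np.asarray(self.axis, dtype=float)
        if X.ndim != 2:
            raise ValueError("matrix must be 2-D (samples × features)")
        if len(self.labels) != X.shape[0]:
            raise ValueError("one label per sample required")
        if axis.size != X.shape[1]:
            raise ValueError("axis length must equal the feature count")
        object.__setattr__(self, "matrix", X)
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "labels", tuple(self.labels))

    @classmethod
    def from_spectra(cls, spectra, labels) -> "SpectralDataset":
        spectra = list(spectra)
        axis = spectra[0].wavenumbers
        for s in spectra[1:]:
            if s.wavenumbers.shape != axis.shape or not np.allclose(s.wavenumbers, axis):
                raise ValueError("all spectra must share one wavenumber axis")
        return cls(np.vstack([s.intensities for s in spectra]), tuple(labels), axis)

    @property
    def class_names(self) -> tuple:
        seen: dict = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return tuple(seen)

    def subset(self, idx) -> "SpectralDataset":
        idx = np.asarray(idx)
        return SpectralDataset(self.matrix[idx], tuple(self.labels[i] for i in idx), self.axis)


@dataclass(frozen=True)
class Diagnosis:
    """Predicted class, per-class continuous responses, and the binary
    positive call under the current threshold."""

    label: str
    scores: dict
    positive: bool


@dataclass(frozen=True)
class PLSDAModel:
    """Fitted PLS-DA model: latent-variable arrays, per-class regression
    coefficients, and the decision threshold on the positive class."""

    n_components: int
    class_names: tuple
    axis: np.ndarray
    x_mean: np.ndarray
    x_weights: np.ndarray       # (n_features, n_components)
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_rotations: np.ndarray
    coef: np.ndarray            # (n_classes, n_features)
    intercept: np.ndarray       # (n_classes,)
    threshold: float = 0.5
    positive_class: str | None = None

    def with_threshold(self, threshold: float, positive_class: str | None = None) -> "PLSDAModel":
        return replace(self, threshold=float(threshold),
                       positive_class=positive_class or self.positive_class)

    def scores_matrix(self, X: np.ndarray) -> np.ndarray:
        """Latent-variable (LV) scores for plotting/inspection."""
        return (np.asarray(X, float) - self.x_mean) @ self.x_rotations

    def responses(self, X: np.ndarray) -> np.ndarray:
        # coef applies to mean-centered features; intercept is the Y mean
        return (np.asarray(X, float) - self.x_mean) @ self.coef.T + self.intercept

    def to_json(self, path) -> None:
        payload = {
            "n_components": self.n_components,
            "class_names": list(self.class_names),
            "axis": self.axis.tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_weights": self.x_weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "x_rotations": self.x_rotations.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
            "threshold": self.threshold,
            "positive_class": self.positive_class,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PLSDAModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            n_components=int(d["n_components"]),
            class_names=tuple(d["class_names"]),
            axis=np.asarray(d["axis"], float),
            x_mean=np.asarray(d["x_mean"], float),
            x_weights=np.asarray(d["x_weights"], float),
            x_loadings=np.asarray(d["x_loadings"], float),
            y_loadings=np.asarray(d["y_loadings"], float),
            x_rotations=np.asarray(d["x_rotations"], float),
            coef=np.asarray(d["coef"], float),
            intercept=np.asarray(d["intercept"], float),
            threshold=float(d["threshold"]),
            positive_class=d["positive_class"],
        )


def _one_hot(labels, class_names) -> np.ndarray:
    index = {c: j for j, c in enumerate(class_names)}
    Y = np.zeros((len(labels), len(class_names)))
    for i, lab in enumerate(labels):
        Y[i, index[lab]] = 1.0
    return Y


def fit_plsda(data: SpectralDataset, n_components: int = 2,
              threshold: float = 0.5, positive_class: str | None = None) -> PLSDAModel:
    """Fit a PLS2 regression of one-hot labels on mean-centered spectra.

    Features are mean-centered but not variance-scaled (the spectra are
    already normalized).  Deterministic given dataset order.
    """
    classes = data.class_names
    if len(classes) < 2:
        raise ValueError("model fitting requires at least two classes")
    counts = {c: data.labels.count(c) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError("each class needs at least two samples")
    max_comp = min(data.matrix.shape[0] - 1, data.matrix.shape[1])
    if not 1 <= n_components <= max_comp:
        raise ValueError(f"n_components must be in [1, {max_comp}]")
    Y = _one_hot(data.labels, classes)
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(data.matrix, Y)
    return PLSDAModel(
        n_components=n_components,
        class_names=classes,
        axis=data.axis,
        x_mean=np.asarray(pls._x_mean, float),
        x_weights=pls.x_weights_,
        x_loadings=pls.x_loadings_,
        y_loadings=pls.y_loadings_,
        x_rotations=pls.x_rotations_,
        coef=pls.coef_,
        intercept=pls.intercept_,
        threshold=float(threshold),
        positive_class=positive_class or classes[0],
    )


def predict(model: PLSDAModel, spectrum) -> Diagnosis:
    """Diagnose one preprocessed spectrum.

    The label is the argmax of the per-class responses; ``positive`` is the
    thresholded response of the designated positive class (monotone in the
    threshold: lowering it never flips a positive call to negative).
    """
    if isinstance(spectrum, RamanSpectrum):
        if spectrum.wavenumbers.shape != model.axis.shape or not np.allclose(
            spectrum.wavenumbers, model.axis
        ):
            raise ValueError("spectrum axis does not match the model axis")
        x = spectrum.intensities
    else:
        x = np.asarray(spectrum, dtype=float)
        if x.shape != model.axis.shape:
            raise ValueError("feature vector length does not match the model axis")
    resp = model.responses(x[None, :])[0]
    scores = {c: float(v) for c, v in zip(model.class_names, resp)}
    label = model.class_names[int(np.argmax(resp))]
    positive = scores[model.positive_class] >= model.threshold
    return Diagnosis(label=label, scores=scores, positive=positive)


@dataclass(frozen=True)
class CVResult:
    """Venetian-blinds cross-validation report."""

    overall_accuracy: float
    per_class_accuracy: dict
    confusion: pd.DataFrame
    n_splits: int
    predictions: tuple


def venetian_blinds_cv(data: SpectralDataset, n_components: int = 2,
                       n_splits: int = 10) -> CVResult:
    """Cross-validate with interleaved (Venetian-blinds) folds.

    Fold f holds the samples whose dataset index ≡ f (mod n_splits); the
    model is refit without that fold and evaluated on it.  If n_splits
    exceeds the smallest class size it is reduced to it, so every training
    split keeps every class.
    """
    n = data.matrix.shape[0]
    if n_splits < 2:
        raise ValueError("n_splits must be >= 2")
    if n_splits > n:
        raise ValueError("n_splits cannot exceed the sample count")
    counts = {c: data.labels.count(c) for c in data.class_names}
    n_splits = min(n_splits, min(counts.values()))
    n_splits = max(n_splits, 2)
    idx = np.arange(n)
    preds = [None] * n
    for f in range(n_splits):
        test = idx[idx % n_splits == f]
        train = idx[idx % n_splits != f]
        model = fit_plsda(data.subset(train), n_components=n_components)
        resp = model.responses(data.matrix[test])
        for i, r in zip(test, resp):
            preds[i] = model.class_names[int(np.argmax(r))]
    labels = list(data.labels)
    classes = data.class_names
    confusion = pd.DataFrame(0, index=list(classes), columns=list(classes))
    for true, pred in zip(labels, preds):
        confusion.loc[true, pred] += 1
    per_class = {c: float(confusion.loc[c, c] / counts[c]) for c in classes}
    overall = float(np.mean([t == p for t, p in zip(labels, preds)]))
    return CVResult(overall_accuracy=overall, per_class_accuracy=per_class,
                    confusion=confusion, n_splits=n_splits, predictions=tuple(preds))


def pca_scores(data: SpectralDataset, n_pcs: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Mean-centered PCA scores and explained-variance fractions."""
    max_pcs = min(data.matrix.shape[0] - 1, data.matrix.shape[1])
    if not 1 <= n_pcs <= max_pcs:
        raise ValueError(f"n_pcs must be in [1, {max_pcs}]")
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(data.matrix)
    return scores, pca.explained_variance_ratio_
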