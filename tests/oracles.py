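"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — dense linear algebra, explicit
convolution, eigen-decompositions on tiny matrices — and shares no code
with the package paths it checks.
"""

import numpy as np


def dense_whittaker(y, lam, p, iters, diff_order):
    """Asymmetric penalized least squares via a dense normal-equation solve."""
    y = np.asarray(y, dtype=float)
    n = y.size
    D = np.diff(np.eye(n), diff_order, axis=0)
    penalty = lam * (D.T @ D)
    w = np.ones(n)
    z = y.copy()
    for _ in range(iters):
        W = np.diag(w)
        z = np.linalg.solve(W + penalty, w * y)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def moving_average_interior(y, frame):
    """Centered moving average, valid (interior) points only."""
    kernel = np.ones(frame) / frame
    return np.convolve(np.asarray(y, float), kernel, mode="valid")


def eigen_pls2(X, Y, n_components):
    """PLS2 by successive dominant eigenvectors of Xᵀ Y Yᵀ X (deflation on X
    and Y). Returns (x_weights, x_scores), defined up to per-component sign."""
    X = np.asarray(X, float) - np.asarray(X, float).mean(axis=0)
    Y = np.asarray(Y, float) - np.asarray(Y, float).mean(axis=0)
    Xr, Yr = X.copy(), Y.copy()
    weights, scores = [], []
    for _ in range(n_components):
        M = Xr.T @ Yr @ Yr.T @ Xr
        evals, evecs = np.linalg.eigh(M)
        w = evecs[:, -1]
        t = Xr @ w
        p = Xr.T @ t / (t @ t)
        q = Yr.T @ t / (t @ t)
        Xr = Xr - np.outer(t, p)
        Yr = Yr - np.outer(t, q)
        weights.append(w)
        scores.append(t)
    return np.array(weights).T, np.array(scores).T


def eigen_pca(X, n_components):
    """PCA scores and explained-variance fractions via the covariance
    eigen-decomposition."""
    X = np.asarray(X, float)
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scores = Xc @ evecs[:, :n_components]
    ratio = evals[:n_components] / evals.sum()
    return scores, ratio


def shoelace_area(vertices):
    v = np.asarray(vertices, float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def rotate(points, angle_rad, center=(0.0, 0.0)):
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    R = np.array([[c, -s], [s, c]])
    pts = np.asarray(points, float) - center
    return pts @ R.T + center
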