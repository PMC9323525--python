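"""Exploratory PCA of absorbance matrices and unfolded EEMs.

Plain SVD-based PCA on mean-centered (optionally autoscaled) data, with
explained-variance reporting and a leave-one-out predictive-residual
table for rank assessment. Centering-only is the default, the usual
choice for spectral blocks whose variables share units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SpectralMatrix
from .errors import DimensionError, FormatError

__all__ = ["PCAModel", "fit_pca", "cross_validate_pca"]


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, SpectralMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DimensionError("X must be a 2-D samples x variables matrix")
    if not np.all(np.isfinite(X)):
        raise FormatError(
            "X contains missing values; fill (interpolate) before PCA"
        )
    return X


def _preprocess(X: np.ndarray, preprocessing: str):
    mean = X.mean(axis=0)
    if preprocessing == "mean_center":
        return X - mean, mean, None
    if preprocessing == "autoscale":
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise FormatError("autoscale impossible: constant variable present")
        return (X - mean) / sd, mean, sd
    raise FormatError(f"unknown preprocessing '{preprocessing}'")


@dataclass
class PCAModel:
    """SVD-based principal components of a preprocessed data matrix."""

    loadings: np.ndarray  # variables x components, orthonormal columns
    scores: np.ndarray  # samples x components
    explained_variance_percent: np.ndarray
    preprocessing: str
    mean: np.ndarray
    scale: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, X) -> np.ndarray:
        X = _as_matrix(X) - self.mean
        if self.scale is not None:
            X = X / self.scale
        return X @ self.loadings


def fit_pca(
    X, preprocessing: str = "mean_center", n_components: int | None = None
) -> PCAModel:
    """PCA by singular value decomposition of the preprocessed matrix.

    Deterministic up to sign, resolved by making each loading's
    largest-magnitude element positive. Explained variance per component
    is the squared singular value as a percentage of the total
    preprocessed sum of squares.
    """
    X = _as_matrix(X)
    n, p = X.shape
    if n < 2:
        raise DimensionError("PCA needs at least 2 samples")
    rank_cap = min(n - 1, p)
    k = rank_cap if n_components is None else int(n_components)
    if k < 1 or k > rank_cap:
        raise DimensionError(
            f"n_components={k} outside [1, min(n-1, p)] = [1, {rank_cap}]"
        )
    Xc, mean, scale = _preprocess(X, preprocessing)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_ss = float((s**2).sum())
    loadings = Vt[:k].T
    for f in range(k):  # sign convention
        j = np.argmax(np.abs(loadings[:, f]))
        if loadings[j, f] < 0:
            loadings[:, f] *= -1.0
    scores = Xc @ loadings
    evp = 100.0 * s[:k] ** 2 / total_ss if total_ss > 0 else np.zeros(k)
    return PCAModel(loadings, scores, evp, preprocessing, mean, scale)


def cross_validate_pca(
    X, max_components: int, preprocessing: str = "mean_center"
) -> pd.DataFrame:
    """Leave-one-out predictive residual (PRESS) per candidate rank.

    For every left-out sample a PCA is fitted on the rest; the sample is
    centered with the training mean, projected on the first ``r``
    loadings, and the squared reconstruction residual accumulated. The
    table reports PRESS and its per-sample root mean square for each
    rank; no automatic rank choice is made.
    """
    X = _as_matrix(X)
    n, p = X.shape
    if n < 3:
        raise DimensionError("LOO cross-validation needs at least 3 samples")
    rmax = min(int(max_components), n - 2, p)
    press = np.zeros(rmax)
    for i in range(n):
        train = np.delete(X, i, axis=0)
        model = fit_pca(train, preprocessing=preprocessing,
                        n_components=min(rmax, train.shape[0] - 1))
        x = X[i] - model.mean
        if model.scale is not None:
            x = x / model.scale
        t = x @ model.loadings
        for r in range(1, rmax + 1):
            rr = min(r, model.n_components)
            resid = x - model.loadings[:, :rr] @ t[:rr]
            press[r - 1] += float(resid @ resid)
    return pd.DataFrame(
        {
            "n_components": np.arange(1, rmax + 1),
            "press": press,
            "rmse": np.sqrt(press / (n * p)),
        }
    ).set_index("n_components")
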