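"""Zero-mean normalization, PCA dimension reduction and whitening.

Voxel time courses (columns of the observation matrix) are treated as
M-dimensional feature vectors.  The across-voxel mean curve is removed, the
M x M temporal covariance is eigendecomposed, the smallest number ``w`` of
leading components retaining at least the requested variance fraction
(default 99%) is kept, and the reduced coordinates are rescaled so their
sample covariance is the identity.  Whitening makes every retained component
contribute on an equal scale to squared-Euclidean dissimilarities, which is
what the hierarchical-clustering initializer relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PCAModel:
    """Eigendecomposition of the temporal covariance of centered data."""

    mean_curve: np.ndarray          # M-vector subtracted from every column
    eigenvalues: np.ndarray         # descending, length M
    eigenvectors: np.ndarray        # M x M orthonormal columns
    w: int                          # retained dimension
    variance_retained: float

    @property
    def components(self) -> np.ndarray:
        """M x w matrix of the retained eigenvector columns."""
        return self.eigenvectors[:, : self.w]


@dataclass
class WhitenedData:
    """w x N whitened coordinates Y with cov(Y) = I."""

    values: np.ndarray              # w x N
    transform: np.ndarray           # w x M, maps centered data -> Y
    inverse_transform: np.ndarray   # M x w, maps Y -> centered data

    @property
    def w(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


def zero_mean(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the across-column mean vector; returns (centered, mean_curve)."""
    values = np.asarray(values, dtype=float)
    if values.shape[1] < 2:
        raise ValueError("need at least 2 columns to center")
    mean_curve = values.mean(axis=1)
    return values - mean_curve[:, None], mean_curve


def fit_pca(centered: np.ndarray, var_threshold: float = 0.99,
            mean_curve: np.ndarray | None = None) -> PCAModel:
    """Eigendecompose the M x M covariance of centered data.

    ``w`` is the smallest k whose cumulative eigenvalue fraction reaches
    ``var_threshold``.  Covariance uses the N-1 divisor.
    """
    centered = np.asarray(centered, dtype=float)
    m, n = centered.shape
    cov = centered @ centered.T / (n - 1)
    if not np.all(np.isfinite(cov)):
        raise ValueError("non-finite covariance")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    if total <= 0:
        raise ValueError("zero-variance data")
    frac = np.cumsum(evals) / total
    w = int(np.searchsorted(frac, var_threshold - 1e-12) + 1)
    w = min(w, m)
    if mean_curve is None:
        mean_curve = np.zeros(m)
    return PCAModel(mean_curve=np.asarray(mean_curve, dtype=float),
                    eigenvalues=evals, eigenvectors=evecs, w=w,
                    variance_retained=float(frac[w - 1]))


def whiten(centered: np.ndarray, model: PCAModel) -> WhitenedData:
    """Project onto the retained components and rescale to unit variance.

    Y = diag(lambda_1..w)^(-1/2) . E_w^T . X_centered, so cov(Y) = I_w.
    """
    lam = model.eigenvalues[: model.w]
    if lam[-1] <= 1e-12 * max(lam[0], 1e-300):
        raise ValueError("rank deficient: zero eigenvalue among retained components")
    scale = 1.0 / np.sqrt(lam)
    transform = scale[:, None] * model.components.T
    inverse = model.components * np.sqrt(lam)[None, :]
    values = transform @ np.asarray(centered, dtype=float)
    return WhitenedData(values=values, transform=transform, inverse_transform=inverse)


def project_pca(centered: np.ndarray, model: PCAModel) -> np.ndarray:
    """PCA-only coordinates (no variance rescaling): E_w^T . X_centered."""
    return model.components.T @ np.asarray(centered, dtype=float)


def reconstruct(Y: WhitenedData, model: PCAModel) -> np.ndarray:
    """Map whitened coordinates back to the original signal space."""
    return Y.inverse_transform @ Y.values + model.mean_curve[:, None]
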