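"""End-to-end segmentation pipeline over an observation matrix.

Chains zero-mean normalization, PCA retaining at least 99% of the variance,
whitening, hierarchical-clustering (or random-sampling) initialization and
EM over the Gaussian mixture, returning the fitted :class:`MixtureResults`.
"""

from __future__ import annotations

import numpy as np

from .cluster import hc_init, random_init_momg
from .decomposition import fit_pca, project_pca, whiten, zero_mean
from .mixture import MixtureResults, PerfusionMixture, select_k


def reduce_matrix(values: np.ndarray, var_threshold: float = 0.99,
                  coordinates: str = "whitened"):
    """Center, reduce and (by default) whiten an M x N observation matrix.

    Returns ``(Y, pca_model)`` with Y the w x N feature matrix in the chosen
    coordinates ("whitened" or "pca").
    """
    centered, mean_curve = zero_mean(np.asarray(values, dtype=float))
    model = fit_pca(centered, var_threshold, mean_curve=mean_curve)
    if coordinates == "whitened":
        Y = whiten(centered, model).values
    elif coordinates == "pca":
        Y = project_pca(centered, model)
    else:
        raise ValueError(f"unknown coordinates {coordinates!r}")
    return Y, model


def segment_matrix(values: np.ndarray, K: int, initializer: str = "hc",
                   seed: int = 0, var_threshold: float = 0.99,
                   coordinates: str | None = None,
                   tol: float = 1e-6, max_iter: int = 500) -> MixtureResults:
    """Segment the columns of an M x N matrix into K tissue classes.

    The HC initializer runs on whitened coordinates; the random-sampling
    baseline runs on PCA coordinates (matching how it samples its means)
    unless ``coordinates`` overrides this.
    """
    if coordinates is None:
        coordinates = "whitened" if initializer == "hc" else "pca"
    Y, _ = reduce_matrix(values, var_threshold, coordinates)
    if initializer == "hc":
        init, _ = hc_init(Y, K, rng=np.random.default_rng(seed))
    elif initializer == "random":
        init = random_init_momg(Y, K, seed)
    else:
        raise ValueError(f"unknown initializer {initializer!r}")
    return PerfusionMixture(Y, K).fit(init, tol=tol, max_iter=max_iter)


def segment_select_k(values: np.ndarray, k_range: tuple[int, int],
                     initializer: str = "hc", seed: int = 0,
                     var_threshold: float = 0.99,
                     tol: float = 1e-6, max_iter: int = 500):
    """Fit every K in ``k_range`` and return (best_K, fits) by minimal MDL."""
    coordinates = "whitened" if initializer == "hc" else "pca"
    Y, _ = reduce_matrix(values, var_threshold, coordinates)
    return select_k(Y, k_range, initializer=initializer, seed=seed,
                    tol=tol, max_iter=max_iter)
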