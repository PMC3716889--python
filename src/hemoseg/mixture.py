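"""EM fitting of a mixture of multivariate Gaussians over reduced voxel features.

The segmentation model treats each tissue class as a multivariate Gaussian in
the whitened feature space, so the data distribution is a K-component mixture

    p(x) = sum_i alpha_i N(x; mu_i, Sigma_i),   sum_i alpha_i = 1.

:class:`PerfusionMixture` is the model object (data plus component count);
``fit()`` runs EM from a supplied or automatically built initialization and
returns a :class:`MixtureResults` carrying the estimates, the log-likelihood
trace, MAP labels, the MDL score and a ``summary()`` table.  ``select_k``
fits a range of K and picks the MDL minimizer.

All densities are evaluated in log space (Cholesky factorization plus the
max-subtraction trick), so heavily mismatched components never produce NaN
responsibilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

from .cluster import MoMGInit, hc_init, random_init_momg, _ridge

# a class whose total responsibility falls below EMPTY_FRAC * N is reseeded
EMPTY_FRAC = 1e-10


@dataclass
class MoMGParams:
    """Mixture parameters theta = (alpha_i, mu_i, Sigma_i), i = 1..K."""

    proportions: np.ndarray   # (K,)
    means: np.ndarray         # (K, w)
    covariances: np.ndarray   # (K, w, w)

    @property
    def K(self) -> int:
        return self.proportions.shape[0]

    @property
    def w(self) -> int:
        return self.means.shape[1]

    @property
    def n_free_parameters(self) -> int:
        """(K-1) weights + K*w means + K*w(w+1)/2 covariance entries."""
        K, w = self.K, self.w
        return (K - 1) + K * w + K * w * (w + 1) // 2


def log_gaussian_density(x: np.ndarray, mean: np.ndarray,
                         cov: np.ndarray) -> float | np.ndarray:
    """log N(x; mean, cov) via Cholesky; ``x`` may be (w,) or (w, n)."""
    x = np.asarray(x, dtype=float)
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    w = mean.shape[0]
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError("covariance is not symmetric positive definite") from err
    dev = (x.reshape(w, -1) if x.ndim > 1 else x[:, None]) - mean[:, None]
    u = solve_triangular(L, dev, lower=True)
    maha = np.sum(u ** 2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    out = -0.5 * (w * np.log(2 * np.pi) + logdet + maha)
    return out if x.ndim > 1 else float(out[0])


def _log_component_densities(Y: np.ndarray, params: MoMGParams) -> np.ndarray:
    """(K, N) matrix of log alpha_i + log N(x_n; mu_i, Sigma_i)."""
    K, N = params.K, Y.shape[1]
    out = np.empty((K, N))
    with np.errstate(divide="ignore"):
        log_alpha = np.log(params.proportions)
    for i in range(K):
        out[i] = log_alpha[i] + log_gaussian_density(Y, params.means[i],
                                                     params.covariances[i])
    return out


def e_step(Y: np.ndarray, params: MoMGParams) -> tuple[np.ndarray, float]:
    """Posterior responsibilities p(i | x_n, theta) and the data log-likelihood."""
    log_joint = _log_component_densities(Y, params)
    log_norm = logsumexp(log_joint, axis=0)
    post = np.exp(log_joint - log_norm)
    return post, float(np.sum(log_norm))


def m_step(Y: np.ndarray, post: np.ndarray,
           ridge: float | None = None) -> MoMGParams:
    """Responsibility-weighted moment updates; vanishing classes are reseeded.

    alpha_i = mean_n p_in, mu_i = weighted mean, Sigma_i = weighted scatter
    plus a ridge multiple of the identity.  A class whose total weight
    vanishes is reseeded at the point the current model explains worst.
    """
    Y = np.asarray(Y, dtype=float)
    w, N = Y.shape
    K = post.shape[0]
    if ridge is None:
        ridge = _ridge(Y)
    weights = post.sum(axis=1)
    proportions = weights / N
    means = np.empty((K, w))
    covs = np.empty((K, w, w))
    for i in range(K):
        if weights[i] < EMPTY_FRAC * N:
            # reseed at the least-responsible point; broad covariance
            worst = int(np.argmin(post.max(axis=0)))
            means[i] = Y[:, worst]
            centered = Y - Y.mean(axis=1, keepdims=True)
            covs[i] = centered @ centered.T / (N - 1) + ridge * np.eye(w)
            proportions[i] = 1.0 / N
            continue
        means[i] = Y @ post[i] / weights[i]
        dev = Y - means[i][:, None]
        covs[i] = (dev * post[i]) @ dev.T / weights[i] + ridge * np.eye(w)
    proportions = proportions / proportions.sum()
    return MoMGParams(proportions=proportions, means=means, covariances=covs)


@dataclass
class MixtureResults:
    """EM fit: final parameters, labels, trace and model-selection score."""

    model: "PerfusionMixture"
    params: MoMGParams
    loglik_trace: np.ndarray
    converged: bool
    posteriors: np.ndarray = field(repr=False)

    @property
    def n_iter(self) -> int:
        return len(self.loglik_trace)

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    @property
    def labels(self) -> np.ndarray:
        """MAP class per column (the maximum-posterior tissue label)."""
        return np.argmax(self.posteriors, axis=0)

    @property
    def mdl(self) -> float:
        """Description-length score -LL + (P_K / 2) ln N; lower is better."""
        return mdl_score(self)

    def summary(self) -> str:
        lines = [
            "Gaussian mixture segmentation (EM)",
            "=" * 44,
            f"components (K): {self.params.K:>6d}   features (w): {self.params.w}",
            f"observations:   {self.model.n_obs:>6d}",
            f"log-likelihood: {self.loglik:>14.2f}",
            f"MDL score:      {self.mdl:>14.2f}",
            f"iterations:     {self.n_iter:>6d}   converged: {self.converged}",
            "-" * 44,
            f"{'class':>5} {'weight':>8} {'n_map':>7} {'|mean|':>8}",
        ]
        counts = np.bincount(self.labels, minlength=self.params.K)
        for i in range(self.params.K):
            lines.append(f"{i:>5d} {self.params.proportions[i]:>8.4f} "
                         f"{counts[i]:>7d} "
                         f"{np.linalg.norm(self.params.means[i]):>8.3f}")
        return "\n".join(lines)


class PerfusionMixture:
    """Mixture-of-Gaussians segmentation model over reduced voxel features.

    Parameters
    ----------
    Y : ndarray
        w x N feature matrix (whitened or PCA coordinates; columns = voxels).
    n_components : int
        Number of tissue classes K.
    """

    def __init__(self, Y: np.ndarray, n_components: int):
        self.Y = np.asarray(Y, dtype=float)
        if self.Y.ndim != 2:
            raise ValueError("Y must be w x N")
        self.n_components = int(n_components)
        if not (1 <= self.n_components <= self.Y.shape[1]):
            raise ValueError("n_components out of range")

    @property
    def n_obs(self) -> int:
        return self.Y.shape[1]

    def fit(self, init: MoMGInit | MoMGParams | None = None, *,
            initializer: str = "hc", seed: int = 0,
            tol: float = 1e-6, max_iter: int = 500) -> MixtureResults:
        """Run EM to convergence of the relative log-likelihood change.

        ``init`` may be explicit parameters; otherwise ``initializer`` picks
        Ward hierarchical clustering ("hc") or the random-column baseline
        ("random", seeded).
        """
        if init is None:
            if initializer == "hc":
                init, _ = hc_init(self.Y, self.n_components)
            elif initializer == "random":
                init = random_init_momg(self.Y, self.n_components, seed)
            else:
                raise ValueError(f"unknown initializer {initializer!r}")
        params = MoMGParams(proportions=np.asarray(init.proportions, float).copy(),
                            means=np.asarray(init.means, float).copy(),
                            covariances=np.asarray(init.covariances, float).copy())
        ridge = _ridge(self.Y)
        trace: list[float] = []
        converged = False
        post, ll = e_step(self.Y, params)
        trace.append(ll)
        for _ in range(max_iter):
            params = m_step(self.Y, post, ridge=ridge)
            post, ll = e_step(self.Y, params)
            trace.append(ll)
            if abs(trace[-1] - trace[-2]) < tol * abs(trace[-2]):
                converged = True
                break
        return MixtureResults(model=self, params=params,
                              loglik_trace=np.asarray(trace),
                              converged=converged, posteriors=post)


def mdl_score(fit: MixtureResults, n_obs: int | None = None) -> float:
    """Minimum-description-length score of a fitted mixture.

    score = -LL + (P_K / 2) ln N with P_K the free-parameter count of the
    K-component mixture (weights, means, full covariances).
    """
    n = fit.model.n_obs if n_obs is None else n_obs
    return -fit.loglik + 0.5 * fit.params.n_free_parameters * np.log(n)


def select_k(Y: np.ndarray, k_range: tuple[int, int], *,
             initializer: str = "hc", seed: int = 0,
             tol: float = 1e-6, max_iter: int = 500
             ) -> tuple[int, list[MixtureResults]]:
    """Fit every K in ``k_range`` (inclusive) and return the MDL argmin.

    Ties break toward the smaller K.
    """
    k_min, k_max = k_range
    if not (1 <= k_min <= k_max <= np.asarray(Y).shape[1]):
        raise ValueError("invalid k_range")
    fits = [PerfusionMixture(Y, k).fit(initializer=initializer, seed=seed,
                                       tol=tol, max_iter=max_iter)
            for k in range(k_min, k_max + 1)]
    scores = [f.mdl for f in fits]
    best = int(np.argmin(scores))  # argmin returns the first (smallest K) on ties
    return k_min + best, fits
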