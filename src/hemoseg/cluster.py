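"""Ward-linkage hierarchical clustering used to initialize the Gaussian mixture.

On whitened feature vectors the squared-Euclidean dissimilarity weights every
retained component equally, so agglomerating with Ward's minimum-variance
criterion produces compact clusters that line up well with tissue classes.
Cutting the tree at K clusters and taking per-cluster moments supplies the
initial mixture weights, means and covariances for EM.  A random-sampling
baseline initializer (means drawn from data columns) is provided for
comparison benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

# Clusters with fewer than 2 members (or degenerate scatter) fall back to a
# ridge multiple of the identity; ridge = RIDGE_FACTOR * trace(global cov)/w.
RIDGE_FACTOR = 1e-6

# HC needs the O(N^2) dissimilarity structure; above this many columns the
# tree is built on a seeded uniform subsample and the remaining columns are
# assigned to the nearest cut-cluster centroid.
DEFAULT_SUBSAMPLE_CAP = 20000


@dataclass
class LinkageTree:
    """Agglomeration record: one row per merge.

    ``merges`` has rows ``(cluster_a, cluster_b, ward_distance, new_size)``
    where ward_distance is the between-cluster distance
    ``n_p n_q / (n_p + n_q) * ||c_p - c_q||^2`` at the time of merging, and
    clusters >= leaf_count index previously formed merges (scipy convention).
    """

    merges: np.ndarray
    leaf_count: int
    _scipy_linkage: np.ndarray = None

    def __post_init__(self):
        if self.merges.shape[0] != self.leaf_count - 1:
            raise ValueError("a tree on N leaves must have N-1 merges")


@dataclass
class ClusterAssignment:
    """Per-column class labels 0..K-1 with every class nonempty."""

    labels: np.ndarray
    K: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(self.K)):
            raise ValueError("labels must cover 0..K-1 with no empty class")


@dataclass
class MoMGInit:
    """Initial mixture parameters: weights, means and SPD covariances."""

    proportions: np.ndarray   # (K,)
    means: np.ndarray         # (K, w)
    covariances: np.ndarray   # (K, w, w)

    @property
    def K(self) -> int:
        return self.proportions.shape[0]


def pairwise_sq_euclidean(values: np.ndarray, max_n: int = DEFAULT_SUBSAMPLE_CAP
                          ) -> np.ndarray:
    """Full N x N squared-Euclidean dissimilarity matrix of the columns."""
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    if n > max_n:
        raise MemoryError(
            f"{n} columns exceed the pairwise cap {max_n}; subsample first")
    return squareform(pdist(values.T, metric="sqeuclidean"))


def ward_distance(size_p: int, size_q: int, centroid_p: np.ndarray,
                  centroid_q: np.ndarray) -> float:
    """Between-cluster Ward distance n_p n_q/(n_p+n_q) * ||c_p - c_q||^2."""
    diff = np.asarray(centroid_p, float) - np.asarray(centroid_q, float)
    return size_p * size_q / (size_p + size_q) * float(diff @ diff)


def ward_linkage(values: np.ndarray) -> LinkageTree:
    """Build the Ward agglomeration tree over the columns of ``values``.

    Uses scipy's nearest-neighbor-chain implementation; scipy reports merge
    heights h with h^2 = 2 * (Ward between-cluster distance), which are
    converted back to the between-cluster distance convention here.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    if n < 2:
        raise ValueError("need at least 2 columns")
    Z = hierarchy.linkage(values.T, method="ward")
    merges = Z.copy()
    merges[:, 2] = Z[:, 2] ** 2 / 2.0
    return LinkageTree(merges=merges, leaf_count=n, _scipy_linkage=Z)


def cut_tree(tree: LinkageTree, K: int) -> ClusterAssignment:
    """Undo the last K-1 merges; classes numbered by first column occurrence."""
    if not (1 <= K <= tree.leaf_count):
        raise ValueError(f"K={K} out of range 1..{tree.leaf_count}")
    raw = hierarchy.cut_tree(tree._scipy_linkage, n_clusters=K).ravel()
    return ClusterAssignment(labels=_relabel_by_first_occurrence(raw), K=K)


def _relabel_by_first_occurrence(labels: np.ndarray) -> np.ndarray:
    _, first_idx = np.unique(labels, return_index=True)
    order = labels[np.sort(first_idx)]
    remap = np.empty(labels.max() + 1, dtype=int)
    remap[order] = np.arange(order.size)
    return remap[labels]


def init_momg(values: np.ndarray, assignment: ClusterAssignment) -> MoMGInit:
    """Per-cluster frequencies/means/covariances as initial mixture parameters.

    Sample covariances get a ridge ``RIDGE_FACTOR * trace(global cov)/w * I``
    so that singleton or degenerate clusters still give SPD matrices.
    """
    values = np.asarray(values, dtype=float)
    w, n = values.shape
    K = assignment.K
    ridge = _ridge(values)
    proportions = np.empty(K)
    means = np.empty((K, w))
    covs = np.empty((K, w, w))
    for k in range(K):
        members = values[:, assignment.labels == k]
        nk = members.shape[1]
        proportions[k] = nk / n
        means[k] = members.mean(axis=1)
        if nk >= 2:
            centered = members - means[k][:, None]
            covs[k] = centered @ centered.T / (nk - 1) + ridge * np.eye(w)
        else:
            covs[k] = ridge * np.eye(w)
    return MoMGInit(proportions=proportions, means=means, covariances=covs)


def _ridge(values: np.ndarray) -> float:
    w, n = values.shape
    centered = values - values.mean(axis=1, keepdims=True)
    global_trace = float(np.sum(centered ** 2)) / max(n - 1, 1)
    return max(RIDGE_FACTOR * global_trace / w, 1e-12)


def hc_init(values: np.ndarray, K: int, subsample_cap: int = DEFAULT_SUBSAMPLE_CAP,
            rng: np.random.Generator | None = None
            ) -> tuple[MoMGInit, ClusterAssignment]:
    """Ward tree -> cut at K -> moment initialization, with a size cap.

    If the column count exceeds ``subsample_cap`` the tree is built on a
    seeded uniform subsample and remaining columns join the nearest
    cut-cluster centroid before the moments are computed.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    if n <= subsample_cap:
        tree = ward_linkage(values)
        assignment = cut_tree(tree, K)
        return init_momg(values, assignment), assignment
    rng = rng or np.random.default_rng(0)
    chosen = np.sort(rng.choice(n, size=subsample_cap, replace=False))
    tree = ward_linkage(values[:, chosen])
    sub_assignment = cut_tree(tree, K)
    centroids = np.stack([values[:, chosen][:, sub_assignment.labels == k].mean(axis=1)
                          for k in range(K)])
    d2 = (np.sum(values ** 2, axis=0)[None, :] - 2 * centroids @ values
          + np.sum(centroids ** 2, axis=1)[:, None])
    labels = np.argmin(d2, axis=0)
    labels[chosen] = sub_assignment.labels
    assignment = ClusterAssignment(labels=_relabel_by_first_occurrence(labels), K=K)
    return init_momg(values, assignment), assignment


def random_init_momg(values: np.ndarray, K: int,
                     seed: int | np.random.Generator = 0) -> MoMGInit:
    """Baseline initializer: K distinct data columns as means.

    Covariances are all set to the global sample covariance and the weights
    are uniform; this mirrors random sampling of columns from the reduced
    data matrix.
    """
    values = np.asarray(values, dtype=float)
    w, n = values.shape
    if K > n:
        raise ValueError(f"K={K} exceeds the number of columns {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols = rng.choice(n, size=K, replace=False)
    centered = values - values.mean(axis=1, keepdims=True)
    global_cov = centered @ centered.T / (n - 1) + _ridge(values) * np.eye(w)
    return MoMGInit(proportions=np.full(K, 1.0 / K),
                    means=values[:, cols].T.copy(),
                    covariances=np.repeat(global_cov[None], K, axis=0))
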