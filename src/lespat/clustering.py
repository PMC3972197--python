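"""Self-tuning spectral clustering and a plain K-means baseline.

Spectral clustering follows the NJW recipe: locally scaled Gaussian affinity,
symmetric normalized Laplacian, top-K eigenvectors row-normalized to the unit
sphere, K-means in that eigenspace. The affinity uses per-point scales
σ_i = distance to the 7th nearest neighbour, which adapts to clusters of very
different densities — the situation lesion-pattern data is in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

DEFAULT_LOCAL_SCALE_NEIGHBOR = 7


@dataclass
class ClusterModel:
    """A fitted partition of the feature-matrix rows."""

    labels: np.ndarray
    n_clusters: int
    centroids: np.ndarray
    algorithm: str
    seed: int
    objective: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        counts = np.bincount(self.labels, minlength=self.n_clusters)
        if np.any(counts == 0):
            raise ValueError("every cluster must be non-empty")

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)


def _relabel_by_size(labels: np.ndarray, k: int) -> np.ndarray:
    """Relabel so cluster 0 is the largest; ties broken by first appearance."""
    counts = np.bincount(labels, minlength=k)
    first_seen = np.full(k, labels.size)
    for i, lab in enumerate(labels):
        if first_seen[lab] == labels.size:
            first_seen[lab] = i
    order = sorted(range(k), key=lambda c: (-counts[c], first_seen[c]))
    mapping = np.empty(k, dtype=int)
    for new, old in enumerate(order):
        mapping[old] = new
    return mapping[labels]


def self_tuning_affinity(
    X: np.ndarray,
    *,
    scale_neighbor: int = DEFAULT_LOCAL_SCALE_NEIGHBOR,
) -> np.ndarray:
    """Locally scaled affinity A_ij = exp(−d²_ij / (σ_i σ_j)), zero diagonal.

    σ_i is the Euclidean distance from point i to its ``scale_neighbor``-th
    nearest neighbour; with fewer points (or coincident points) it is clamped
    to the smallest positive distance so duplicates get affinity 1.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    D = squareform(pdist(X))
    sorted_d = np.sort(D, axis=1)  # column 0 is the self-distance 0
    idx = min(scale_neighbor, n - 1)
    sigma = sorted_d[:, idx].copy()
    positive = D[D > 0]
    fallback = positive.min() if positive.size else 1.0
    sigma[sigma <= 0] = fallback
    A = np.exp(-(D**2) / np.outer(sigma, sigma))
    np.fill_diagonal(A, 0.0)
    return A


def normalized_laplacian(A: np.ndarray) -> np.ndarray:
    """Symmetric normalized Laplacian L = I − D^{−1/2} A D^{−1/2}."""
    deg = A.sum(axis=1)
    inv_sqrt = np.where(deg > 0, deg, 1.0) ** -0.5
    L = -A * inv_sqrt[:, None] * inv_sqrt[None, :]
    np.fill_diagonal(L, 1.0 - np.diag(A) * inv_sqrt**2)
    return L


def _spectral_embedding(A: np.ndarray, k: int) -> np.ndarray:
    """Top-k eigenvectors of D^{−1/2} A D^{−1/2}, rows normalized to unit length."""
    deg = A.sum(axis=1)
    inv_sqrt = np.where(deg > 0, deg, 1.0) ** -0.5
    M = A * inv_sqrt[:, None] * inv_sqrt[None, :]
    vals, vecs = np.linalg.eigh(M)
    # deterministic ordering: descending eigenvalue, sign fixed by first nonzero entry
    order = np.argsort(vals)[::-1][:k]
    V = vecs[:, order]
    for j in range(V.shape[1]):
        col = V[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            V[:, j] = -col
    norms = np.linalg.norm(V, axis=1)
    norms[norms == 0] = 1.0
    return V / norms[:, None]


def spectral_cluster(
    X: np.ndarray,
    k: int,
    seed: int,
    *,
    scale_neighbor: int = DEFAULT_LOCAL_SCALE_NEIGHBOR,
    n_init: int = 50,
) -> ClusterModel:
    """NJW spectral clustering with K-means in the row-normalized eigenspace."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    if k == n:
        labels = np.arange(n)
        return ClusterModel(labels=labels, n_clusters=k, centroids=X.copy(),
                            algorithm="spectral", seed=seed, objective=0.0)
    A = self_tuning_affinity(X, scale_neighbor=scale_neighbor)
    Y = _spectral_embedding(A, k)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(Y)
    labels = _relabel_by_size(km.labels_, k)
    centroids = np.stack([X[labels == c].mean(axis=0) for c in range(k)])
    return ClusterModel(
        labels=labels,
        n_clusters=k,
        centroids=centroids,
        algorithm="spectral",
        seed=seed,
        objective=float(km.inertia_),
    )


def kmeans_cluster(
    X: np.ndarray,
    k: int,
    seed: int,
    *,
    n_init: int = 50,
) -> ClusterModel:
    """K-means (k-means++ init, multiple restarts) directly in feature space."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    labels = km.labels_
    # sklearn can, in degenerate cases, leave a cluster empty only if k > unique
    # points; repair by re-seeding at the farthest point from its centroid.
    counts = np.bincount(labels, minlength=k)
    if np.any(counts == 0):
        centers = km.cluster_centers_
        for c in np.flatnonzero(counts == 0):
            dist = np.linalg.norm(X - centers[labels], axis=1)
            far = int(np.argmax(dist))
            labels[far] = c
            dist[far] = -1
        counts = np.bincount(labels, minlength=k)
    labels = _relabel_by_size(labels, k)
    centroids = np.stack([X[labels == c].mean(axis=0) for c in range(k)])
    return ClusterModel(
        labels=labels,
        n_clusters=k,
        centroids=centroids,
        algorithm="kmeans",
        seed=seed,
        objective=float(km.inertia_),
    )


def cluster(X: np.ndarray, k: int, seed: int, algorithm: str = "spectral", **kwargs) -> ClusterModel:
    if algorithm == "spectral":
        return spectral_cluster(X, k, seed, **kwargs)
    if algorithm == "kmeans":
        return kmeans_cluster(X, k, seed, **kwargs)
    raise ValueError(f"unknown algorithm {algorithm!r}")
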