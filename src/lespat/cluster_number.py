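"""Cluster-number estimation: four validity indices fused by a rounded mean.

The four votes are the Dunn index, the Calinski-Harabasz index, the gap
statistic (uniform bounding-box references, 1-SE rule; the only index that can
vote k = 1 directly) and the eigengap of the normalized Laplacian of the
self-tuning affinity. The fused estimate is the nearest integer of the mean of
the votes, halves rounding away from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

from .clustering import DEFAULT_LOCAL_SCALE_NEIGHBOR, normalized_laplacian, self_tuning_affinity

INDEX_NAMES = ("dunn", "calinski_harabasz", "gap", "affinity_eigen")


@dataclass
class ValidityReport:
    """Per-index cluster-number votes and their fused estimate."""

    votes: dict[str, int]
    k_range: tuple[int, int]
    fused_k: int
    seed: int | None = None
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.k_range
        for name, k in self.votes.items():
            if not lo <= k <= hi:
                raise ValueError(f"vote {name}={k} outside searched range {self.k_range}")


def dunn_index(X: np.ndarray, labels: np.ndarray) -> float:
    """min inter-cluster (single-linkage) distance over max intra-cluster diameter.

    Returns +inf when every cluster is a singleton (all diameters zero).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("Dunn index requires at least 2 clusters")
    D = squareform(pdist(X))
    min_between = np.inf
    max_diameter = 0.0
    for i, a in enumerate(clusters):
        ia = labels == a
        max_diameter = max(max_diameter, D[np.ix_(ia, ia)].max(initial=0.0))
        for b in clusters[i + 1 :]:
            ib = labels == b
            min_between = min(min_between, D[np.ix_(ia, ib)].min())
    if max_diameter == 0.0:
        return math.inf
    return min_between / max_diameter


def calinski_harabasz(X: np.ndarray, labels: np.ndarray) -> float:
    """[trace(B)/(K−1)] / [trace(W)/(n−K)]; +inf when within-scatter is zero."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    k = np.unique(labels).size
    if not 2 <= k < n:
        raise ValueError(f"Calinski-Harabasz requires 2 <= K < n, got K={k}, n={n}")
    within = 0.0
    for c in np.unique(labels):
        pts = X[labels == c]
        within += ((pts - pts.mean(axis=0)) ** 2).sum()
    if within == 0.0:
        return math.inf
    return float(calinski_harabasz_score(X, labels))


def _pooled_within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    """W_k = Σ_clusters Σ_members ||x − centroid||² (log-argument of the gap)."""
    total = 0.0
    for c in np.unique(labels):
        pts = X[labels == c]
        total += ((pts - pts.mean(axis=0)) ** 2).sum()
    return total


def _kmeans_labels(X: np.ndarray, k: int, seed: int, n_init: int) -> np.ndarray:
    if k == 1:
        return np.zeros(X.shape[0], dtype=int)
    return KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X).labels_


def gap_statistic(
    X: np.ndarray,
    k_range: tuple[int, int],
    n_references: int = 100,
    seed: int = 0,
    *,
    n_init: int = 10,
    reference: str = "pca",
) -> int:
    """Gap-statistic estimate with the 1-SE rule.

    Gap(k) = E*[log W_k] − log W_k with uniform box references; the chosen k
    is the smallest with Gap(k) ≥ Gap(k+1) − s_{k+1}. k = 1 is an admissible
    answer, which the other indices cannot give.

    ``reference`` picks the null box: "pca" aligns it with the data's
    principal axes (recommended for elongated feature clouds, where the
    axis-aligned box badly over-estimates k); "uniform" is the plain
    bounding-box variant.
    """
    if n_references < 10:
        raise ValueError("need at least 10 reference datasets")
    if reference not in ("pca", "uniform"):
        raise ValueError(f"unknown reference {reference!r}")
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    lo, hi = k_range
    lo = max(lo, 1)
    hi = min(hi, X.shape[0] - 1)
    if np.all(X == X[0]):
        return 1
    ks = list(range(lo, hi + 1))

    if reference == "pca":
        mean = X.mean(axis=0)
        _, _, Vt = np.linalg.svd(X - mean, full_matrices=False)
        Xp = (X - mean) @ Vt.T
        mins, maxs = Xp.min(axis=0), Xp.max(axis=0)
        ref_sets = [
            rng.uniform(mins, maxs, size=Xp.shape) @ Vt + mean for _ in range(n_references)
        ]
    else:
        mins, maxs = X.min(axis=0), X.max(axis=0)
        ref_sets = [rng.uniform(mins, maxs, size=X.shape) for _ in range(n_references)]

    log_w = np.empty(len(ks))
    gap = np.empty(len(ks))
    sk = np.empty(len(ks))
    for j, k in enumerate(ks):
        labels = _kmeans_labels(X, k, seed, n_init)
        log_w[j] = np.log(max(_pooled_within_dispersion(X, labels), 1e-300))
        ref_logs = np.empty(n_references)
        for b, ref in enumerate(ref_sets):
            # references get the same optimization effort as the data; an
            # under-optimized reference W_k inflates Gap at large k
            rlab = _kmeans_labels(ref, k, seed + b + 1, n_init)
            ref_logs[b] = np.log(max(_pooled_within_dispersion(ref, rlab), 1e-300))
        gap[j] = ref_logs.mean() - log_w[j]
        sk[j] = ref_logs.std() * math.sqrt(1.0 + 1.0 / n_references)

    for j in range(len(ks) - 1):
        if gap[j] >= gap[j + 1] - sk[j + 1]:
            return ks[j]
    return ks[-1]


def affinity_eigen_estimate(
    X: np.ndarray,
    k_max: int,
    *,
    scale_neighbor: int = DEFAULT_LOCAL_SCALE_NEIGHBOR,
) -> int:
    """Largest eigengap of the normalized Laplacian of the self-tuning affinity.

    With c well-separated components the Laplacian has c near-zero eigenvalues
    followed by a jump; the position of the largest gap within 1..k_max is the
    estimate.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 points")
    A = self_tuning_affinity(X, scale_neighbor=scale_neighbor)
    L = normalized_laplacian(A)
    vals = np.sort(np.linalg.eigvalsh(L))
    k_max = min(k_max, vals.size - 1)
    gaps = vals[1 : k_max + 1] - vals[:k_max]
    return int(np.argmax(gaps)) + 1


def decision_fusion(votes: list[int]) -> int:
    """Nearest integer of the mean vote; halves round away from zero."""
    if not votes:
        raise ValueError("need at least one vote")
    mean = sum(votes) / len(votes)
    return int(math.floor(mean + 0.5))


def _argmax_index_vote(
    X: np.ndarray,
    k_values: list[int],
    index_fn,
    seed: int,
    n_init: int,
) -> tuple[int, dict[int, float]]:
    scores: dict[int, float] = {}
    for k in k_values:
        labels = _kmeans_labels(X, k, seed, n_init)
        if np.unique(labels).size < 2:
            continue
        scores[k] = index_fn(X, labels)
    best = max(scores, key=lambda k: (scores[k], -k))
    return best, scores


def estimate_k(
    X: np.ndarray,
    k_range: tuple[int, int] = (1, 6),
    *,
    seed: int = 0,
    n_references: int = 100,
    n_init: int = 10,
    scale_neighbor: int = DEFAULT_LOCAL_SCALE_NEIGHBOR,
) -> ValidityReport:
    """Run all four indices over the searched range and fuse their votes.

    Dunn and Calinski-Harabasz need K ≥ 2, so their votes are the argmax over
    k ≥ 2 (candidate partitions from seeded K-means); the gap statistic and
    the eigengap may vote k = 1.
    """
    X = np.asarray(X, dtype=float)
    lo, hi = k_range
    hi = min(hi, X.shape[0] - 1)
    ks_ge2 = [k for k in range(max(lo, 2), hi + 1)]
    if not ks_ge2:
        raise ValueError(f"k_range {k_range} leaves no candidates >= 2 for n={X.shape[0]}")

    dunn_k, dunn_scores = _argmax_index_vote(X, ks_ge2, dunn_index, seed, n_init)
    ch_k, ch_scores = _argmax_index_vote(X, ks_ge2, calinski_harabasz, seed, n_init)
    gap_k = gap_statistic(X, (lo, hi), n_references=n_references, seed=seed, n_init=n_init)
    eig_k = affinity_eigen_estimate(X, hi, scale_neighbor=scale_neighbor)
    eig_k = max(eig_k, lo)

    votes = {
        "dunn": dunn_k,
        "calinski_harabasz": ch_k,
        "gap": gap_k,
        "affinity_eigen": eig_k,
    }
    return ValidityReport(
        votes=votes,
        k_range=(lo, hi),
        fused_k=decision_fusion(list(votes.values())),
        seed=seed,
        details={"dunn_scores": dunn_scores, "calinski_harabasz_scores": ch_scores},
    )
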