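"""Cluster-separation statistic and randomization/permutation significance tests.

The separation S averages, over cluster pairs, the centroid distance
normalized by the spread of the pooled pair members around the pooled
centroid. Significance is assessed by comparing the observed S against null
partitions: i.i.d. uniform labels (randomization) or shuffles of the observed
label multiset (permutation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SeparationTestResult:
    S_observed: float
    n_permutations: int
    p_randomization: float | None
    p_permutation: float | None
    seed: int

    def __post_init__(self) -> None:
        for p in (self.p_randomization, self.p_permutation):
            if p is not None and not (0 < p <= 1):
                raise ValueError(f"p-value out of (0, 1]: {p}")
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")


def cluster_separation(X: np.ndarray, labels: np.ndarray) -> float:
    """S = (2/(K(K−1))) Σ_{a<b} ||c_a − c_b|| / σ_ab.

    σ_ab is the standard deviation of distances of the pooled members of
    clusters a and b to the pooled centroid. Translation invariant; S = 0 for
    coincident centroids; +inf if a pooled pair is a set of identical points.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    K = clusters.size
    if K < 2:
        raise ValueError("separation needs at least 2 clusters")
    members = [X[labels == c] for c in clusters]
    centroids = [m.mean(axis=0) for m in members]
    total = 0.0
    for a in range(K):
        for b in range(a + 1, K):
            d = float(np.linalg.norm(centroids[a] - centroids[b]))
            pooled = np.vstack([members[a], members[b]])
            pooled_centroid = pooled.mean(axis=0)
            sigma = float(np.linalg.norm(pooled - pooled_centroid, axis=1).std())
            if sigma == 0.0:
                if d == 0.0:
                    continue  # identical coincident clusters separate by 0
                return float("inf")
            total += d / sigma
    return total * 2.0 / (K * (K - 1))


def _random_labels(rng: np.random.Generator, n: int, K: int) -> np.ndarray:
    """i.i.d. uniform labels over 0..K−1; redraw until no cluster is empty."""
    while True:
        labels = rng.integers(0, K, size=n)
        if np.bincount(labels, minlength=K).min() > 0:
            return labels


def separation_test(
    X: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 10_000,
    mode: str = "both",
    seed: int = 0,
) -> SeparationTestResult:
    """Rank p-value of the observed separation under one or both null models.

    p = (1 + #{S_null ≥ S_obs}) / (1 + n_perm); the add-one keeps p > 0.
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100")
    if mode not in ("randomization", "permutation", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    K = np.unique(labels).size
    n = X.shape[0]
    S_obs = cluster_separation(X, labels)
    rng = np.random.default_rng(seed)

    def tail(draw) -> float:
        exceed = 0
        for _ in range(n_perm):
            if cluster_separation(X, draw()) >= S_obs:
                exceed += 1
        return (1 + exceed) / (1 + n_perm)

    p_rand = None
    p_perm = None
    if mode in ("randomization", "both"):
        p_rand = tail(lambda: _random_labels(rng, n, K))
    if mode in ("permutation", "both"):
        base = labels.copy()
        p_perm = tail(lambda: rng.permutation(base))
    return SeparationTestResult(
        S_observed=S_obs,
        n_permutations=n_perm,
        p_randomization=p_rand,
        p_permutation=p_perm,
        seed=seed,
    )


def pairwise_separation_tests(
    X: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 10_000,
    mode: str = "both",
    seed: int = 0,
) -> dict[tuple[int, int], SeparationTestResult]:
    """Run the separation test for each cluster pair in isolation."""
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    out: dict[tuple[int, int], SeparationTestResult] = {}
    for i, a in enumerate(clusters):
        for b in clusters[i + 1 :]:
            keep = (labels == a) | (labels == b)
            out[(int(a), int(b))] = separation_test(
                X[keep], labels[keep], n_perm=n_perm, mode=mode, seed=seed
            )
    return out
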