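"""Tier 2: patient cluster-cardinality profiles and outcome regression.

Each patient with active lesions is summarised by how many of their lesion
trajectories fall in each tier-1 cluster. A no-intercept least-squares model
maps these counts to the follow-up outcome volume; goodness of fit is
reported as in-sample R² and leave-one-out (patient or lesion) R².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment


@dataclass
class PatientProfile:
    """Cluster cardinalities and outcome volumes for one patient."""

    patient_id: str
    cardinalities: np.ndarray
    hypointense_ml: float
    tll_ml: float | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        self.cardinalities = np.asarray(self.cardinalities, dtype=int)
        if np.any(self.cardinalities < 0):
            raise ValueError("cardinalities must be non-negative")
        if self.hypointense_ml < 0:
            raise ValueError("outcome volume must be >= 0")

    @property
    def n_trajectories(self) -> int:
        return int(self.cardinalities.sum())


@dataclass
class LooResult:
    """Leave-one-out summary: pooled predictive R² plus per-fold mean/variance."""

    pooled_r2: float
    fold_mean: float
    fold_variance: float
    n_folds: int
    n_skipped: int = 0


@dataclass
class RegressionFit:
    beta: np.ndarray
    r2_full: float
    r2_loo_patient: LooResult | None = None
    r2_loo_lesion: LooResult | None = None
    intercept: float = 0.0
    details: dict = field(default_factory=dict)


def patient_cardinalities(
    labels: Sequence[int],
    trajectory_patients: Mapping[str, str] | Sequence[str],
    K: int,
    trajectory_ids: Sequence[str] | None = None,
    outcomes: Mapping[str, tuple[float, float | None]] | None = None,
) -> list[PatientProfile]:
    """Count each patient's trajectories per cluster.

    ``trajectory_patients`` maps trajectory id → patient id (or is a parallel
    sequence of patient ids). Patients present in ``outcomes`` but owning no
    trajectory are emitted with zero cardinalities and flagged group "C".
    """
    labels = np.asarray(labels, dtype=int)
    if isinstance(trajectory_patients, Mapping):
        if trajectory_ids is None:
            raise ValueError("trajectory_ids required with a mapping")
        patients = [trajectory_patients[tid] for tid in trajectory_ids]
    else:
        patients = list(trajectory_patients)
    if len(patients) != labels.size:
        raise ValueError("labels and patient assignments must align")

    counts: dict[str, np.ndarray] = {}
    for pid, lab in zip(patients, labels):
        if not 0 <= lab < K:
            raise ValueError(f"label {lab} outside 0..{K - 1}")
        counts.setdefault(pid, np.zeros(K, dtype=int))[lab] += 1

    all_patients = sorted(counts)
    if outcomes is not None:
        all_patients = sorted(set(all_patients) | set(outcomes))
    profiles = []
    for pid in all_patients:
        card = counts.get(pid, np.zeros(K, dtype=int))
        hypo, tll = (outcomes or {}).get(pid, (0.0, None))
        profiles.append(
            PatientProfile(
                patient_id=pid,
                cardinalities=card,
                hypointense_ml=hypo,
                tll_ml=tll,
                group=None if pid in counts else "C",
            )
        )
    return profiles


def active_profiles(profiles: Sequence[PatientProfile]) -> list[PatientProfile]:
    """Drop zero-lesion (group C) patients, which are excluded from fitting."""
    return [p for p in profiles if p.n_trajectories > 0]


def design_matrix(profiles: Sequence[PatientProfile]) -> tuple[np.ndarray, np.ndarray]:
    active = active_profiles(profiles)
    N = np.stack([p.cardinalities for p in active]).astype(float)
    y = np.array([p.hypointense_ml for p in active], dtype=float)
    return N, y


def fit_linear_no_intercept(N: np.ndarray, y: np.ndarray) -> np.ndarray:
    """beta = argmin ||Nβ − y||², minimum-norm under rank deficiency."""
    N = np.atleast_2d(np.asarray(N, dtype=float))
    y = np.asarray(y, dtype=float)
    if N.shape[0] != y.shape[0]:
        raise ValueError(f"dimension mismatch: {N.shape[0]} rows vs {y.shape[0]} outcomes")
    if N.shape[0] < 1 or not np.any(N):
        raise ValueError("design matrix is empty or all-zero")
    beta, *_ = np.linalg.lstsq(N, y, rcond=None)
    return beta


def r_squared(y_pred: np.ndarray, y_obs: np.ndarray) -> float:
    """1 − SS_res/SS_tot; can be negative out of sample."""
    y_pred = np.asarray(y_pred, dtype=float)
    y_obs = np.asarray(y_obs, dtype=float)
    if y_pred.shape != y_obs.shape or y_obs.size < 2:
        raise ValueError("need equal-length vectors of size >= 2")
    ss_tot = ((y_obs - y_obs.mean()) ** 2).sum()
    if ss_tot == 0:
        raise ValueError("R² undefined for constant observations")
    ss_res = ((y_obs - y_pred) ** 2).sum()
    return 1.0 - ss_res / ss_tot


def loo_patient_cv(profiles: Sequence[PatientProfile]) -> LooResult:
    """Leave one patient out, refit, predict the held-out outcome.

    ``pooled_r2`` scores the pooled out-of-sample predictions against the
    observed outcomes. A single held-out point has no R² of its own, so the
    per-fold mean/variance summarise each fold's training-set R² (fit
    stability across folds).
    """
    N, y = design_matrix(profiles)
    n = N.shape[0]
    if n < 3:
        raise ValueError("need at least 3 active patients")
    preds = np.empty(n)
    fold_r2 = []
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        beta = fit_linear_no_intercept(N[keep], y[keep])
        preds[i] = N[i] @ beta
        fold_r2.append(r_squared(N[keep] @ beta, y[keep]))
    fold_r2 = np.asarray(fold_r2)
    return LooResult(
        pooled_r2=r_squared(preds, y),
        fold_mean=float(fold_r2.mean()),
        fold_variance=float(fold_r2.var()),
        n_folds=n,
    )


def match_cluster_labels(
    ref_centroids: np.ndarray, centroids: np.ndarray
) -> np.ndarray:
    """Map cluster ids of a refit onto reference ids by closest-centroid assignment."""
    cost = np.linalg.norm(ref_centroids[:, None, :] - centroids[None, :, :], axis=2)
    ref_idx, new_idx = linear_sum_assignment(cost)
    mapping = np.empty(centroids.shape[0], dtype=int)
    mapping[new_idx] = ref_idx
    return mapping


def loo_lesion_cv(
    X: np.ndarray,
    trajectory_patients: Sequence[str],
    outcomes: Mapping[str, tuple[float, float | None]],
    K: int,
    cluster_fn: Callable[[np.ndarray, int], "object"],
    reference_model,
) -> LooResult:
    """Leave one lesion trajectory out, re-cluster at fixed K, refit, score.

    Cluster correspondence between the refit and the reference partition is
    re-established by matching centroids (Hungarian assignment). A fold that
    cannot sustain K non-empty clusters is skipped and counted. Each fold's R²
    is computed on the full active cohort with the fold's coefficients;
    ``pooled_r2`` here is the mean of those per-fold values.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < K + 1:
        raise ValueError("need more trajectories than clusters")
    patients = list(trajectory_patients)
    fold_r2 = []
    skipped = 0
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        try:
            model = cluster_fn(X[keep], K)
        except ValueError:
            skipped += 1
            continue
        if np.unique(model.labels).size < K:
            skipped += 1
            continue
        mapping = match_cluster_labels(reference_model.centroids, model.centroids)
        labels = mapping[model.labels]
        fold_patients = [p for j, p in enumerate(patients) if keep[j]]
        profiles = patient_cardinalities(labels, fold_patients, K, outcomes=outcomes)
        N, y = design_matrix(profiles)
        beta = fit_linear_no_intercept(N, y)
        # score on the full cohort under the reference partition
        full_profiles = patient_cardinalities(
            reference_model.labels, patients, K, outcomes=outcomes
        )
        Nf, yf = design_matrix(full_profiles)
        fold_r2.append(r_squared(Nf @ beta, yf))
    if not fold_r2:
        raise ValueError("all leave-one-lesion folds failed")
    fold_r2 = np.asarray(fold_r2)
    return LooResult(
        pooled_r2=float(fold_r2.mean()),
        fold_mean=float(fold_r2.mean()),
        fold_variance=float(fold_r2.var()),
        n_folds=len(fold_r2),
        n_skipped=skipped,
    )


def fit_patient_model(
    profiles: Sequence[PatientProfile],
    *,
    with_intercept: bool = False,
) -> RegressionFit:
    """Fit the no-intercept model on active patients and report in-sample R²."""
    N, y = design_matrix(profiles)
    if with_intercept:
        Na = np.hstack([N, np.ones((N.shape[0], 1))])
        coef = fit_linear_no_intercept(Na, y)
        beta, intercept = coef[:-1], float(coef[-1])
        preds = Na @ coef
    else:
        beta = fit_linear_no_intercept(N, y)
        intercept = 0.0
        preds = N @ beta
    return RegressionFit(beta=beta, r2_full=r_squared(preds, y), intercept=intercept)
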