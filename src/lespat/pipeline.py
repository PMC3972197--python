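"""End-to-end orchestration of the two-tier analysis.

Stages: observation matching → trajectory features → cluster-number fusion →
clustering → separation test → patient profiles → no-intercept regression
with leave-one-out R². Every stage is deterministic given the configured
seed, and the result bundle carries the per-stage artifacts plus counts for
auditing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cluster_number import ValidityReport, estimate_k
from .cluster_stats import SeparationTestResult, separation_test
from .clustering import ClusterModel, cluster
from .features import FeatureMatrix, build_feature_matrix
from .mask_io import Agent, LesionObservation, LesionTrajectory, build_trajectories
from .patient_model import (
    LooResult,
    PatientProfile,
    RegressionFit,
    design_matrix,
    fit_patient_model,
    loo_lesion_cv,
    loo_patient_cv,
    patient_cardinalities,
)

AGENT_SETS = {
    "gd+uspio": (Agent.GD, Agent.USPIO),
    "gd-only": (Agent.GD,),
}


@dataclass
class PipelineConfig:
    """Validated knobs for one pipeline run; serialized with every output."""

    n_timepoints: int = 2
    feature_mode: str = "tensor"  # tensor | volume
    hollow_mode: str = "continuous"  # continuous | binary
    standardize: bool = True
    algorithm: str = "spectral"  # spectral | kmeans
    k: int | str = "auto"
    k_range: tuple[int, int] = (1, 6)
    agent_set: str = "gd+uspio"  # gd+uspio | gd-only
    n_perm: int = 10_000
    gap_references: int = 100
    kmeans_restarts: int = 50
    scan_restarts: int = 10  # restarts used inside validity-index scans
    seed: int = 0
    run_separation_test: bool = True
    run_loo_lesion: bool = False

    def __post_init__(self) -> None:
        if self.feature_mode not in ("tensor", "volume"):
            raise ValueError(f"feature_mode must be tensor|volume, got {self.feature_mode!r}")
        if self.hollow_mode not in ("continuous", "binary"):
            raise ValueError(f"hollow_mode must be continuous|binary, got {self.hollow_mode!r}")
        if self.algorithm not in ("spectral", "kmeans"):
            raise ValueError(f"algorithm must be spectral|kmeans, got {self.algorithm!r}")
        if self.agent_set not in AGENT_SETS:
            raise ValueError(f"agent_set must be one of {sorted(AGENT_SETS)}")
        if self.k != "auto" and (not isinstance(self.k, int) or self.k < 2):
            raise ValueError("k must be 'auto' or an integer >= 2")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    features: FeatureMatrix
    trajectories: list[LesionTrajectory]
    validity: ValidityReport | None
    model: ClusterModel
    separation: SeparationTestResult | None
    profiles: list[PatientProfile]
    fit: RegressionFit
    counts: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.model.n_clusters

    def patient_table(self) -> "object":
        """Per-patient cardinalities, outcomes and group (Table-2 style)."""
        import pandas as pd

        rows = []
        for p in self.profiles:
            rows.append(
                {
                    "patient_id": p.patient_id,
                    **{f"cluster_{c}": int(n) for c, n in enumerate(p.cardinalities)},
                    "n_trajectories": p.n_trajectories,
                    "hypointense_ml": p.hypointense_ml,
                    "tll_ml": p.tll_ml,
                    "group": p.group,
                }
            )
        df = pd.DataFrame(rows)
        return df.sort_values("hypointense_ml", ascending=False).reset_index(drop=True)

    def summary(self) -> dict:
        out = {
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "k": self.k,
            "algorithm": self.model.algorithm,
            "cluster_sizes": self.model.cluster_sizes().tolist(),
            "beta": self.fit.beta.tolist(),
            "r2_full": self.fit.r2_full,
            "counts": self.counts,
        }
        if self.validity is not None:
            out["votes"] = self.validity.votes
            out["fused_k"] = self.validity.fused_k
        if self.separation is not None:
            out["S_observed"] = self.separation.S_observed
            out["p_randomization"] = self.separation.p_randomization
            out["p_permutation"] = self.separation.p_permutation
        if self.fit.r2_loo_patient is not None:
            out["loo_patient"] = asdict(self.fit.r2_loo_patient)
        if self.fit.r2_loo_lesion is not None:
            out["loo_lesion"] = asdict(self.fit.r2_loo_lesion)
        return out


def _assign_groups(profiles: Sequence[PatientProfile], k: int) -> None:
    """Group A: any lesion in a non-dominant (severe-pattern) cluster; B: only
    the dominant cluster; C: no active lesions. Cluster 0 is the largest by
    construction."""
    for p in profiles:
        if p.n_trajectories == 0:
            p.group = "C"
        elif k >= 2 and p.cardinalities[1:].sum() > 0:
            p.group = "A"
        else:
            p.group = "B"


def run_pipeline(
    observations: Sequence[LesionObservation],
    outcomes: Mapping[str, tuple[float, float | None]],
    config: PipelineConfig,
) -> PipelineResult:
    """Run both tiers on matched observations and patient outcomes."""
    by_patient: dict[str, list[LesionObservation]] = {}
    for obs in observations:
        by_patient.setdefault(obs.patient_id, []).append(obs)

    trajectories: list[LesionTrajectory] = []
    for pid in sorted(by_patient):
        trajectories.extend(build_trajectories(by_patient[pid]))

    agents = AGENT_SETS[config.agent_set]
    # a trajectory never observed under the selected agents has no features
    trajectories = [t for t in trajectories if any(t.has_agent(a) for a in agents)]
    if len(trajectories) < 3:
        raise ValueError("need at least 3 trajectories")
    fm = build_feature_matrix(
        trajectories,
        config.n_timepoints,
        mode=config.feature_mode,
        hollow_mode=config.hollow_mode,
        standardize=config.standardize,
        agents=agents,
    )

    validity = None
    if config.k == "auto":
        validity = estimate_k(
            fm.values,
            config.k_range,
            seed=config.seed,
            n_references=config.gap_references,
            n_init=config.scan_restarts,
        )
        k = max(validity.fused_k, 2)  # tier 2 needs at least 2 patterns
    else:
        k = int(config.k)

    model = cluster(
        fm.values, k, config.seed, algorithm=config.algorithm, n_init=config.kmeans_restarts
    )

    separation = None
    if config.run_separation_test:
        separation = separation_test(
            fm.values, model.labels, n_perm=config.n_perm, mode="both", seed=config.seed
        )

    traj_patients = {t.trajectory_id: t.patient_id for t in trajectories}
    profiles = patient_cardinalities(
        model.labels,
        traj_patients,
        k,
        trajectory_ids=fm.row_ids,
        outcomes=dict(outcomes),
    )
    _assign_groups(profiles, k)

    fit = fit_patient_model(profiles)
    fit.r2_loo_patient = loo_patient_cv(profiles)
    if config.run_loo_lesion:
        ordered_patients = [traj_patients[tid] for tid in fm.row_ids]
        active_outcomes = {
            p.patient_id: (p.hypointense_ml, p.tll_ml) for p in profiles if p.n_trajectories > 0
        }
        fit.r2_loo_lesion = loo_lesion_cv(
            fm.values,
            ordered_patients,
            active_outcomes,
            k,
            lambda X, kk: cluster(
                X, kk, config.seed, algorithm=config.algorithm, n_init=config.kmeans_restarts
            ),
            model,
        )

    counts = {
        "n_observations": len(observations),
        "n_trajectories": len(trajectories),
        "n_gd_trajectories": sum(t.has_agent(Agent.GD) for t in trajectories),
        "n_uspio_trajectories": sum(t.has_agent(Agent.USPIO) for t in trajectories),
        "n_patients_total": len(set(outcomes) | set(by_patient)),
        "n_patients_active": sum(p.n_trajectories > 0 for p in profiles),
        "n_patients_excluded": sum(p.n_trajectories == 0 for p in profiles),
    }
    return PipelineResult(
        config=config,
        features=fm,
        trajectories=trajectories,
        validity=validity,
        model=model,
        separation=separation,
        profiles=profiles,
        fit=fit,
        counts=counts,
    )


def experiment_grid(
    observations: Sequence[LesionObservation],
    outcomes: Mapping[str, tuple[float, float | None]],
    base_config: PipelineConfig,
    *,
    feature_modes: Sequence[str] = ("tensor", "volume"),
    algorithms: Sequence[str] = ("spectral", "kmeans"),
    agent_sets: Sequence[str] = ("gd+uspio", "gd-only"),
) -> dict[tuple[str, str, str], LooResult]:
    """Cross every feature mode × algorithm × agent set; report LOO-patient R²."""
    grid: dict[tuple[str, str, str], LooResult] = {}
    for fmode in feature_modes:
        for algo in algorithms:
            for aset in agent_sets:
                cfg = PipelineConfig(
                    **{
                        **asdict(base_config),
                        "feature_mode": fmode,
                        "algorithm": algo,
                        "agent_set": aset,
                        "run_separation_test": False,
                        "run_loo_lesion": False,
                    }
                )
                result = run_pipeline(observations, outcomes, cfg)
                grid[(fmode, algo, aset)] = result.fit.r2_loo_patient
    return grid
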