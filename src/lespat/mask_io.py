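"""Labeled lesion-mask I/O and spatial matching across time points and agents.

Masks are integer-labeled 3D volumes (0 = background, each positive label one
delineated lesion), one volume per (patient, time point, contrast agent).
Volumes are assumed co-registered upstream, so the same physical lesion can be
identified across time points and across agents purely by voxel overlap.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np


class Agent(str, Enum):
    """Contrast agent of an enhanced acquisition."""

    GD = "gd"
    USPIO = "uspio"


@dataclass(frozen=True)
class MaskVolume:
    """One integer-labeled mask volume for (patient, time point, agent)."""

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    patient_id: str
    time_index: int
    agent: Agent

    def __post_init__(self) -> None:
        if self.voxels.ndim != 3:
            raise ValueError(f"mask must be 3D, got {self.voxels.ndim}D")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError(f"mask must be integer-labeled, got {self.voxels.dtype}")
        if self.voxels.min() < 0:
            raise ValueError("mask labels must be non-negative")
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError(f"voxel_size components must be > 0, got {self.voxel_size}")


@dataclass(frozen=True)
class LesionObservation:
    """Voxel set of one lesion at one time point for one agent.

    ``voxel_coords`` holds integer (i, j, k) indices, shape (m, 3); geometry
    downstream converts them to mm via ``voxel_size``.
    """

    patient_id: str
    time_index: int
    agent: Agent
    label: int
    voxel_coords: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        coords = np.asarray(self.voxel_coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("voxel_coords must have shape (m, 3)")
        if coords.shape[0] == 0:
            raise ValueError("voxel_coords must be non-empty")
        if len({tuple(c) for c in coords.tolist()}) != coords.shape[0]:
            raise ValueError("voxel_coords must be unique")
        object.__setattr__(self, "voxel_coords", np.ascontiguousarray(coords, dtype=np.int64))

    @property
    def m(self) -> int:
        """Number of voxels."""
        return int(self.voxel_coords.shape[0])

    def voxel_set(self) -> frozenset[tuple[int, int, int]]:
        return frozenset(map(tuple, self.voxel_coords.tolist()))


@dataclass
class LesionTrajectory:
    """Observations of one physical lesion keyed by (time_index, agent)."""

    patient_id: str
    trajectory_id: str
    observations: dict[tuple[int, Agent], LesionObservation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.observations:
            raise ValueError("trajectory must have at least one observation")
        for obs in self.observations.values():
            if obs.patient_id != self.patient_id:
                raise ValueError("all observations must share the trajectory patient_id")

    def get(self, time_index: int, agent: Agent) -> LesionObservation | None:
        return self.observations.get((time_index, agent))

    def has_agent(self, agent: Agent) -> bool:
        return any(a == agent for (_, a) in self.observations)

    @property
    def max_time_index(self) -> int:
        return max(t for (t, _) in self.observations)


def load_mask_volume(
    path: str | Path,
    patient_id: str,
    time_index: int,
    agent: Agent,
) -> MaskVolume:
    """Load an integer-labeled NIfTI mask; voxel sizes come from the header.

    Raises ``FileNotFoundError`` for missing files and ``ValueError`` for
    non-3D or non-integer-valued data.
    """
    import nibabel as nib

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise ValueError(f"{path}: mask values are not integers")
        data = rounded.astype(np.int32)
    zooms = img.header.get_zooms()[:3]
    return MaskVolume(
        voxels=np.ascontiguousarray(data),
        voxel_size=(float(zooms[0]), float(zooms[1]), float(zooms[2])),
        patient_id=patient_id,
        time_index=time_index,
        agent=agent,
    )


def load_voxel_csv(path: str | Path) -> list[LesionObservation]:
    """Read the plain voxel-list fixture dialect.

    Columns: ``patient,t,agent,label,i,j,k`` with an optional
    ``dx,dy,dz`` triple repeated per row (defaults to 1 mm isotropic).
    """
    rows: dict[tuple[str, int, Agent, int], list[tuple[int, int, int]]] = defaultdict(list)
    sizes: dict[tuple[str, int, Agent, int], tuple[float, float, float]] = {}
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            key = (rec["patient"], int(rec["t"]), Agent(rec["agent"].lower()), int(rec["label"]))
            rows[key].append((int(rec["i"]), int(rec["j"]), int(rec["k"])))
            if "dx" in rec and rec["dx"]:
                sizes[key] = (float(rec["dx"]), float(rec["dy"]), float(rec["dz"]))
    out = []
    for key in sorted(rows, key=lambda k: (k[0], k[1], k[2].value, k[3])):
        patient, t, agent, label = key
        out.append(
            LesionObservation(
                patient_id=patient,
                time_index=t,
                agent=agent,
                label=label,
                voxel_coords=np.array(rows[key], dtype=np.int64),
                voxel_size=sizes.get(key, (1.0, 1.0, 1.0)),
            )
        )
    return out


def extract_observations(volume: MaskVolume, *, binary_components: bool = False) -> list[LesionObservation]:
    """Enumerate one observation per distinct nonzero label, sorted ascending.

    With ``binary_components`` a binary (or single-label) mask is first split
    into 26-connected components, mirroring the fallback for masks that were
    not delineated lesion-by-lesion.
    """
    data = volume.voxels
    if binary_components:
        from scipy import ndimage

        structure = np.ones((3, 3, 3), dtype=bool)
        data, _ = ndimage.label(data > 0, structure=structure)
    labels = np.unique(data)
    labels = labels[labels > 0]
    observations = []
    for label in labels:
        coords = np.argwhere(data == label)
        observations.append(
            LesionObservation(
                patient_id=volume.patient_id,
                time_index=volume.time_index,
                agent=volume.agent,
                label=int(label),
                voxel_coords=coords,
                voxel_size=volume.voxel_size,
            )
        )
    return observations


def _overlap_counts(
    obs_a: Sequence[LesionObservation], obs_b: Sequence[LesionObservation]
) -> dict[tuple[int, int], int]:
    """Voxel-overlap counts for all pairs (index into obs_a, index into obs_b)."""
    sets_b = [o.voxel_set() for o in obs_b]
    counts: dict[tuple[int, int], int] = {}
    for ia, a in enumerate(obs_a):
        sa = a.voxel_set()
        for ib, sb in enumerate(sets_b):
            n = len(sa & sb)
            if n:
                counts[(ia, ib)] = n
    return counts


def _greedy_assign(
    counts: Mapping[tuple[int, int], int],
    obs_a: Sequence[LesionObservation],
    obs_b: Sequence[LesionObservation],
) -> list[tuple[int, int, int]]:
    """One-to-one assignment by descending overlap, ties to smaller labels.

    Returns (index_a, index_b, overlap) triples.
    """
    order = sorted(
        counts.items(),
        key=lambda kv: (-kv[1], obs_a[kv[0][0]].label, obs_b[kv[0][1]].label),
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for (ia, ib), n in order:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        pairs.append((ia, ib, n))
    return pairs


def match_across_time(
    obs_t: Sequence[LesionObservation],
    obs_tnext: Sequence[LesionObservation],
) -> tuple[
    list[tuple[LesionObservation, LesionObservation]],
    list[LesionObservation],
    list[LesionObservation],
]:
    """Match lesions between consecutive time points by voxel overlap.

    Any overlap (≥ 1 voxel) makes two observations the same lesion; when an
    observation overlaps several candidates it goes to the largest overlap
    (ties to the smaller label), one-to-one. Returns
    ``(matched_pairs, unmatched_t, unmatched_tnext)``.
    """
    patients = {o.patient_id for o in obs_t} | {o.patient_id for o in obs_tnext}
    if len(patients) > 1:
        raise ValueError(f"observations from different patients: {sorted(patients)}")
    counts = _overlap_counts(obs_t, obs_tnext)
    pairs = _greedy_assign(counts, obs_t, obs_tnext)
    matched_a = {ia for ia, _, _ in pairs}
    matched_b = {ib for _, ib, _ in pairs}
    matched = [(obs_t[ia], obs_tnext[ib]) for ia, ib, _ in pairs]
    unmatched_t = [o for i, o in enumerate(obs_t) if i not in matched_a]
    unmatched_next = [o for i, o in enumerate(obs_tnext) if i not in matched_b]
    return matched, unmatched_t, unmatched_next


def build_agent_trajectories(
    observations_by_time: Mapping[int, Sequence[LesionObservation]],
    agent: Agent,
) -> list[LesionTrajectory]:
    """Chain per-time observations of a single agent into trajectories.

    Time points are processed in ascending order; each new time point is
    matched against the latest observation of every open trajectory.
    """
    trajectories: list[dict[tuple[int, Agent], LesionObservation]] = []
    latest: list[LesionObservation] = []  # parallel to trajectories

    for t in sorted(observations_by_time):
        obs_t = [o for o in observations_by_time[t] if o.agent == agent]
        if not trajectories:
            for o in obs_t:
                trajectories.append({(t, agent): o})
                latest.append(o)
            continue
        counts = _overlap_counts(latest, obs_t)
        pairs = _greedy_assign(counts, latest, obs_t)
        matched_new = set()
        for itraj, inew, _ in pairs:
            trajectories[itraj][(t, agent)] = obs_t[inew]
            latest[itraj] = obs_t[inew]
            matched_new.add(inew)
        for inew, o in enumerate(obs_t):
            if inew not in matched_new:
                trajectories.append({(t, agent): o})
                latest.append(o)

    out = []
    for idx, obsmap in enumerate(trajectories):
        first = next(iter(obsmap.values()))
        out.append(
            LesionTrajectory(
                patient_id=first.patient_id,
                trajectory_id=f"{first.patient_id}_{agent.value}_{idx}",
                observations=dict(obsmap),
            )
        )
    return out


def pair_across_agents(
    gd_trajs: Sequence[LesionTrajectory],
    uspio_trajs: Sequence[LesionTrajectory],
) -> list[LesionTrajectory]:
    """Merge Gd and USPIO trajectories of the same physical lesion.

    Correspondence is voxel overlap at any shared time point, with the same
    one-to-one maximum-overlap rule as temporal matching. Single-agent
    trajectories are kept; their missing-agent feature blocks are zero-filled
    downstream.
    """
    patients = {t.patient_id for t in gd_trajs} | {t.patient_id for t in uspio_trajs}
    if len(patients) > 1:
        raise ValueError(f"trajectories from different patients: {sorted(patients)}")

    overlaps: dict[tuple[int, int], int] = {}
    for ig, gt in enumerate(gd_trajs):
        gd_by_t = {t: o for (t, _), o in gt.observations.items()}
        for iu, ut in enumerate(uspio_trajs):
            best = 0
            for (t, _), uo in ut.observations.items():
                go = gd_by_t.get(t)
                if go is not None:
                    best = max(best, len(go.voxel_set() & uo.voxel_set()))
            if best:
                overlaps[(ig, iu)] = best

    order = sorted(
        overlaps.items(),
        key=lambda kv: (
            -kv[1],
            min(o.label for o in gd_trajs[kv[0][0]].observations.values()),
            min(o.label for o in uspio_trajs[kv[0][1]].observations.values()),
        ),
    )
    gd_used: set[int] = set()
    us_used: set[int] = set()
    merged: list[LesionTrajectory] = []
    for (ig, iu), _ in order:
        if ig in gd_used or iu in us_used:
            continue
        gd_used.add(ig)
        us_used.add(iu)
        obsmap = dict(gd_trajs[ig].observations)
        obsmap.update(uspio_trajs[iu].observations)
        merged.append(
            LesionTrajectory(
                patient_id=gd_trajs[ig].patient_id,
                trajectory_id=gd_trajs[ig].trajectory_id,
                observations=obsmap,
            )
        )
    for ig, gt in enumerate(gd_trajs):
        if ig not in gd_used:
            merged.append(gt)
    for iu, ut in enumerate(uspio_trajs):
        if iu not in us_used:
            merged.append(ut)
    merged.sort(key=lambda t: t.trajectory_id)
    return merged


def build_trajectories(
    observations: Iterable[LesionObservation],
) -> list[LesionTrajectory]:
    """Full matching for one patient: per-agent temporal chains, then agent pairing."""
    by_agent_time: dict[Agent, dict[int, list[LesionObservation]]] = {
        Agent.GD: defaultdict(list),
        Agent.USPIO: defaultdict(list),
    }
    patients = set()
    for obs in observations:
        patients.add(obs.patient_id)
        by_agent_time[obs.agent][obs.time_index].append(obs)
    if len(patients) > 1:
        raise ValueError(f"observations from different patients: {sorted(patients)}")
    gd = build_agent_trajectories(by_agent_time[Agent.GD], Agent.GD)
    uspio = build_agent_trajectories(by_agent_time[Agent.USPIO], Agent.USPIO)
    return pair_across_agents(gd, uspio)
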