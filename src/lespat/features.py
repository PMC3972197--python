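"""Rotation-invariant shape features per lesion and trajectory feature vectors.

Each observation is reduced to the sorted eigenvalues of the covariance of its
voxel coordinates (in mm, so anisotropic voxels are handled correctly) plus a
hollowness index H = A / A_fill that separates ring-enhancing (H < 1) from
focal (H = 1) lesions. Per trajectory, the per-(agent, time) blocks are
concatenated into a fixed-layout vector with absent blocks zero-filled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .mask_io import Agent, LesionObservation, LesionTrajectory

HollowMode = Literal["continuous", "binary"]
FeatureMode = Literal["tensor", "volume"]

# per-(agent, time) block layout in tensor mode
TENSOR_BLOCK = ("l1", "l2", "l3", "h")


@dataclass(frozen=True)
class ShapeFeatures:
    """Sorted covariance eigenvalues (mm²), hollowness and volume of one observation."""

    eigenvalues: tuple[float, float, float]
    hollowness: float
    volume: float

    def __post_init__(self) -> None:
        l1, l2, l3 = self.eigenvalues
        if not (l1 >= l2 >= l3 >= 0):
            raise ValueError(f"eigenvalues must be sorted non-negative, got {self.eigenvalues}")
        if not (0 < self.hollowness <= 1):
            raise ValueError(f"hollowness must be in (0, 1], got {self.hollowness}")


def centered_coordinate_matrix(obs: LesionObservation, *, coords: np.ndarray | None = None) -> np.ndarray:
    """m×3 matrix of mm coordinates minus their column means.

    ``coords`` overrides the observation's voxel set (used for the
    hole-filled variant); indices are scaled componentwise by voxel size.
    """
    ijk = obs.voxel_coords if coords is None else np.asarray(coords)
    if ijk.shape[0] < 1:
        raise ValueError("observation has no voxels")
    mm = ijk.astype(float) * np.asarray(obs.voxel_size, dtype=float)
    return mm - mm.mean(axis=0)


def covariance_eigenvalues(M: np.ndarray) -> tuple[float, float, float]:
    """Eigenvalues of C = MᵀM/m, sorted descending, clamped at 0.

    Sorting makes the descriptor invariant to orientation; eigenvectors are
    discarded for the same reason.
    """
    m = M.shape[0]
    C = (M.T @ M) / m
    vals = np.linalg.eigvalsh(C)
    vals = np.clip(vals, 0.0, None)
    l3, l2, l1 = float(vals[0]), float(vals[1]), float(vals[2])
    return (l1, l2, l3)


def _fill_slices(obs: LesionObservation) -> np.ndarray:
    """Hole-filled voxel coordinates, filling each axial (constant-k) slice in 2D."""
    coords = obs.voxel_coords
    mins = coords.min(axis=0)
    maxs = coords.max(axis=0)
    shape = maxs - mins + 1
    grid = np.zeros(shape, dtype=bool)
    grid[tuple((coords - mins).T)] = True
    for k in range(shape[2]):
        grid[:, :, k] = ndimage.binary_fill_holes(grid[:, :, k])
    return np.argwhere(grid) + mins


def _fill_3d(obs: LesionObservation) -> np.ndarray:
    coords = obs.voxel_coords
    mins = coords.min(axis=0)
    maxs = coords.max(axis=0)
    grid = np.zeros(maxs - mins + 1, dtype=bool)
    grid[tuple((coords - mins).T)] = True
    grid = ndimage.binary_fill_holes(grid)
    return np.argwhere(grid) + mins


def hollowness_index(obs: LesionObservation, *, fill_3d: bool = False) -> float:
    """H = A / A_fill with per-axial-slice 2D hole filling (3D behind a flag).

    H is 1 for a simply-connected lesion and < 1 when interior holes exist,
    which is what distinguishes ring-enhancing from focal lesions.
    """
    filled = _fill_3d(obs) if fill_3d else _fill_slices(obs)
    return obs.m / filled.shape[0]


def binarize_hollowness(h: float) -> int:
    """Nearest-integer rounding of H to {0, 1}; H ≥ 0.5 → 1."""
    if not (0 < h <= 1):
        raise ValueError(f"hollowness must be in (0, 1], got {h}")
    return 1 if h >= 0.5 else 0


def shape_features(
    obs: LesionObservation,
    *,
    tensor_on_filled: bool = True,
    fill_3d: bool = False,
) -> ShapeFeatures:
    """Eigenvalues + hollowness + volume for one observation.

    By default the covariance is computed on the hole-filled voxel set so a
    ring lesion is represented as the filled body it wraps, while H records
    the hollowness separately.
    """
    h = hollowness_index(obs, fill_3d=fill_3d)
    coords = None
    if tensor_on_filled and h < 1.0:
        coords = _fill_3d(obs) if fill_3d else _fill_slices(obs)
    M = centered_coordinate_matrix(obs, coords=coords)
    eigs = covariance_eigenvalues(M)
    voxel_volume = float(np.prod(obs.voxel_size))
    return ShapeFeatures(eigenvalues=eigs, hollowness=h, volume=obs.m * voxel_volume)


def block_size(mode: FeatureMode) -> int:
    return 4 if mode == "tensor" else 1


def feature_columns(n_timepoints: int, mode: FeatureMode = "tensor") -> list[str]:
    """Stable column names: all Gd blocks for t=0..N−1, then all USPIO blocks."""
    names = []
    for agent in (Agent.GD, Agent.USPIO):
        for t in range(n_timepoints):
            if mode == "tensor":
                names.extend(f"{agent.value}_t{t}_{part}" for part in TENSOR_BLOCK)
            else:
                names.append(f"{agent.value}_t{t}_vol")
    return names


def assemble_trajectory_vector(
    traj: LesionTrajectory,
    n_timepoints: int,
    *,
    mode: FeatureMode = "tensor",
    hollow_mode: HollowMode = "continuous",
    tensor_on_filled: bool = True,
    fill_3d: bool = False,
    agents: Sequence[Agent] = (Agent.GD, Agent.USPIO),
) -> np.ndarray:
    """Per-trajectory feature vector with absent (time, agent) blocks zeroed.

    Tensor mode emits (λ1, λ2, λ3, H) per block; volume mode a single mm³
    scalar. Layout: Gd t=0..N−1 blocks, then USPIO blocks.
    """
    if traj.max_time_index >= n_timepoints:
        raise ValueError(
            f"trajectory {traj.trajectory_id} has time_index {traj.max_time_index} "
            f">= n_timepoints {n_timepoints}"
        )
    values: list[float] = []
    for agent in (Agent.GD, Agent.USPIO):
        for t in range(n_timepoints):
            obs = traj.get(t, agent)
            width = block_size(mode)
            if obs is None or agent not in agents:
                values.extend([0.0] * width)
                continue
            feats = shape_features(obs, tensor_on_filled=tensor_on_filled, fill_3d=fill_3d)
            if mode == "tensor":
                h = feats.hollowness
                if hollow_mode == "binary":
                    h = float(binarize_hollowness(h))
                values.extend([*feats.eigenvalues, h])
            else:
                values.append(feats.volume)
    return np.asarray(values, dtype=float)


@dataclass
class FeatureMatrix:
    """Stacked trajectory feature vectors plus the standardization transform."""

    values: np.ndarray
    row_ids: list[str]
    columns: list[str]
    standardized: bool = False
    column_means: np.ndarray | None = None
    column_scales: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2D")
        if self.values.shape[0] != len(self.row_ids):
            raise ValueError("row_ids length must match row count")
        if self.values.shape[1] != len(self.columns):
            raise ValueError("columns length must match column count")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def constant_columns(self) -> np.ndarray:
        """Boolean mask of columns with zero variance (e.g. agents never seen)."""
        return self.values.std(axis=0) == 0

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.values, columns=self.columns)
        df.insert(0, "trajectory_id", self.row_ids)
        df.to_csv(path, sep="\t", index=False)
        if self.standardized:
            sidecar = Path(path).with_suffix(".standardize.json")
            sidecar.write_text(
                json.dumps(
                    {
                        "column_means": self.column_means.tolist(),
                        "column_scales": self.column_scales.tolist(),
                    },
                    indent=2,
                )
            )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        row_ids = df["trajectory_id"].astype(str).tolist()
        cols = [c for c in df.columns if c != "trajectory_id"]
        fm = cls(values=df[cols].to_numpy(dtype=float), row_ids=row_ids, columns=cols)
        sidecar = Path(path).with_suffix(".standardize.json")
        if sidecar.exists():
            params = json.loads(sidecar.read_text())
            fm.standardized = True
            fm.column_means = np.asarray(params["column_means"], dtype=float)
            fm.column_scales = np.asarray(params["column_scales"], dtype=float)
        return fm


def build_feature_matrix(
    trajectories: Sequence[LesionTrajectory],
    n_timepoints: int,
    *,
    mode: FeatureMode = "tensor",
    hollow_mode: HollowMode = "continuous",
    standardize: bool = True,
    tensor_on_filled: bool = True,
    fill_3d: bool = False,
    agents: Sequence[Agent] = (Agent.GD, Agent.USPIO),
) -> FeatureMatrix:
    """Stack trajectory vectors (stable id order) and optionally standardize.

    Standardization centers each column and scales to unit variance; constant
    columns are centered only (left at 0). The transform parameters are kept
    on the matrix for reproducibility.
    """
    if len(trajectories) < 2:
        raise ValueError("need at least 2 trajectories to build a feature matrix")
    ordered = sorted(trajectories, key=lambda t: t.trajectory_id)
    rows = np.stack(
        [
            assemble_trajectory_vector(
                t,
                n_timepoints,
                mode=mode,
                hollow_mode=hollow_mode,
                tensor_on_filled=tensor_on_filled,
                fill_3d=fill_3d,
                agents=agents,
            )
            for t in ordered
        ]
    )
    fm = FeatureMatrix(
        values=rows,
        row_ids=[t.trajectory_id for t in ordered],
        columns=feature_columns(n_timepoints, mode),
    )
    if standardize:
        means = rows.mean(axis=0)
        scales = rows.std(axis=0)
        safe = np.where(scales == 0, 1.0, scales)
        fm.values = (rows - means) / safe
        fm.standardized = True
        fm.column_means = means
        fm.column_scales = safe
    return fm
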