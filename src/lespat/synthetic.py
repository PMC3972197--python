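"""Synthetic cohorts of labeled lesion masks with known ground truth.

Generates patients with voxelized ellipsoidal and ring-shaped (hollow) lesion
masks over two contrast agents and two time points, following three archetypal
spatio-temporal patterns:

* C1 — lesions of any size enhancing only at the first time point, generally
  Gd-only, focal;
* C2 — medium/large lesions present at both time points with Gd and USPIO
  co-enhancement, focal Gd and ring-like USPIO;
* C3 — medium lesions at the first time point only, both agents non-focal.

Patients come in three groups: A (at least one C2/C3 lesion), B (only C1
lesions) and C (no active lesions). Outcomes follow a known linear model on
the true per-pattern cardinalities so the full pipeline can be scored against
ground truth. Everything is deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .mask_io import Agent, LesionObservation

PATTERN_CLASSES = ("C1", "C2", "C3")

# semi-major-axis ranges (mm) for the qualitative size classes; free
# parameters. Ranges overlap so the cohort size distribution is a continuum
# rather than three disjoint modes.
SIZE_CLASSES: dict[str, tuple[float, float]] = {
    "small": (2.0, 4.0),
    "medium": (2.8, 5.0),
    "large": (3.5, 6.0),
}

# severe-pattern semi-major-axis ranges (mm); C2 sits at the top of the
# cohort size scale, C3 in the upper-medium range
C2_SIZE_RANGE = (8.3, 9.2)
C3_SIZE_RANGE = (5.3, 6.2)

# shell draws (inner/outer scale) per ring context: C1 rings and C3's
# "non completely focal" Gd enhancement are mild, USPIO rings of the severe
# patterns are markedly hollow
SHELL_RANGES = {
    "C1": (0.15, 0.5),
    "C2": (0.45, 0.65),
    "C3_gd": (0.6, 0.75),
    "C3_uspio": (0.6, 0.75),
}


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort; defaults mirror the study's structure."""

    n_patients: int = 25
    n_timepoints: int = 2
    group_counts: tuple[int, int, int] = (5, 13, 7)  # A, B, C
    c1_per_patient: tuple[int, int] = (3, 8)  # inclusive range, group A
    c1_per_patient_b: tuple[int, int] = (2, 9)  # inclusive range, group B
    severe_per_patient: tuple[int, int] = (3, 6)  # C2/C3 lesions per group-A patient
    ring_fraction: float = 0.25  # target share of lesions carrying a ring enhancement
    c1_uspio_prob: float = 0.0  # incidental mild USPIO co-enhancement on C1 lesions
    include_uspio_only: bool = False  # add one USPIO-enhanced lesion without Gd
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    beta_true: tuple[float, float, float] = (0.1, 1.5, 1.0)  # ml per (C1, C2, C3) lesion
    noise_sd: float = 0.1  # ml
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.group_counts) != self.n_patients:
            raise ValueError("group counts must sum to n_patients")
        if not 0 <= self.ring_fraction < 1:
            raise ValueError("ring_fraction must be in [0, 1)")
        if self.severe_per_patient[0] < 1 and self.group_counts[0] > 0:
            raise ValueError("group-A patients need at least one severe lesion")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")


@dataclass
class GroundTruth:
    """Generative truth for scoring: classes, cardinalities, coefficients."""

    lesion_class: dict[tuple[str, int], str]
    obs_to_lesion: dict[tuple[str, int, str, int], tuple[str, int]]
    cardinalities: dict[str, np.ndarray]  # patient -> counts over (C1, C2, C3)
    beta_true: np.ndarray
    noiseless_outcomes: dict[str, float]
    groups: dict[str, str]


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    observations: list[LesionObservation]
    outcomes: dict[str, tuple[float, float]]  # patient -> (hypointense_ml, tll_ml)
    truth: GroundTruth

    @property
    def patient_ids(self) -> list[str]:
        return sorted(self.outcomes)

    def observations_for(self, patient_id: str) -> list[LesionObservation]:
        return [o for o in self.observations if o.patient_id == patient_id]

    def trajectory_truth_class(self, trajectory) -> str:
        """True pattern class of a matched trajectory, via any of its observations."""
        for (t, agent), obs in trajectory.observations.items():
            key = (obs.patient_id, t, agent.value, obs.label)
            lesion = self.truth.obs_to_lesion.get(key)
            if lesion is not None:
                return self.truth.lesion_class[lesion]
        raise KeyError(f"trajectory {trajectory.trajectory_id} not in ground truth")


def _ellipsoid_coords(
    center_mm: np.ndarray,
    semi_axes_mm: np.ndarray,
    rotation: np.ndarray,
    voxel_size: np.ndarray,
    shape: tuple[int, int, int] | None,
) -> np.ndarray:
    """Integer voxel indices whose mm-centers fall inside the rotated ellipsoid."""
    r_max = semi_axes_mm.max()
    lo = np.floor((center_mm - r_max) / voxel_size).astype(int)
    hi = np.ceil((center_mm + r_max) / voxel_size).astype(int)
    if shape is not None:
        clipped_lo = np.maximum(lo, 0)
        clipped_hi = np.minimum(hi, np.asarray(shape) - 1)
        if np.any(clipped_lo != lo) or np.any(clipped_hi != hi):
            warnings.warn("ellipsoid exits volume bounds; mask clipped", stacklevel=2)
        lo, hi = clipped_lo, clipped_hi
    else:
        lo = np.maximum(lo, 0)
    axes = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    mm = grid * voxel_size - center_mm
    local = mm @ rotation  # rotation columns are the ellipsoid axes
    inside = ((local / semi_axes_mm) ** 2).sum(axis=1) <= 1.0
    return grid[inside]


def make_ellipsoid_mask(
    center_mm: Sequence[float],
    semi_axes_mm: Sequence[float],
    rotation: np.ndarray | None = None,
    voxel_size: Sequence[float] = (1.0, 1.0, 1.0),
    shape: tuple[int, int, int] | None = None,
    *,
    patient_id: str = "p0",
    time_index: int = 0,
    agent: Agent = Agent.GD,
    label: int = 1,
) -> LesionObservation:
    """Voxelize a solid (optionally rotated) ellipsoid into a LesionObservation."""
    center = np.asarray(center_mm, dtype=float)
    axes = np.asarray(semi_axes_mm, dtype=float)
    vsize = np.asarray(voxel_size, dtype=float)
    if np.any(axes < vsize.min()):
        raise ValueError("semi-axes must be at least one voxel")
    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    coords = _ellipsoid_coords(center, axes, R, vsize, shape)
    if coords.shape[0] == 0:
        raise ValueError("ellipsoid produced an empty mask")
    return LesionObservation(
        patient_id=patient_id,
        time_index=time_index,
        agent=agent,
        label=label,
        voxel_coords=coords,
        voxel_size=tuple(float(v) for v in vsize),
    )


def make_ring_mask(
    center_mm: Sequence[float],
    semi_axes_mm: Sequence[float],
    shell_fraction: float = 0.6,
    rotation: np.ndarray | None = None,
    voxel_size: Sequence[float] = (1.0, 1.0, 1.0),
    shape: tuple[int, int, int] | None = None,
    *,
    patient_id: str = "p0",
    time_index: int = 0,
    agent: Agent = Agent.GD,
    label: int = 1,
) -> LesionObservation:
    """Hollow lesion: outer ellipsoid minus a concentric copy scaled by shell_fraction.

    If the inner region is empty at coarse resolution, at least one interior
    voxel is removed so hollowness stays < 1.
    """
    if not 0 < shell_fraction < 1:
        raise ValueError("shell_fraction must be in (0, 1)")
    center = np.asarray(center_mm, dtype=float)
    axes = np.asarray(semi_axes_mm, dtype=float)
    vsize = np.asarray(voxel_size, dtype=float)
    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    outer = _ellipsoid_coords(center, axes, R, vsize, shape)
    inner = _ellipsoid_coords(center, axes * shell_fraction, R, vsize, shape)
    outer_set = {tuple(c) for c in outer.tolist()}
    inner_set = {tuple(c) for c in inner.tolist()} & outer_set
    if not inner_set:
        # coarse fallback: carve out the voxel closest to the center
        mm = outer * vsize - center
        inner_set = {tuple(outer[int(np.argmin((mm**2).sum(axis=1)))].tolist())}
    keep = np.array(sorted(outer_set - inner_set), dtype=np.int64)
    if keep.shape[0] == 0:
        raise ValueError("ring mask is empty")
    return LesionObservation(
        patient_id=patient_id,
        time_index=time_index,
        agent=agent,
        label=label,
        voxel_coords=keep,
        voxel_size=tuple(float(v) for v in vsize),
    )


def _draw_c1_axes(rng: np.random.Generator, min_axis: float = 1.0) -> np.ndarray:
    """C1 semi-axes: independent bell-shaped draws spanning small-to-large.

    A single smooth distribution (rather than a mixture over the size
    classes) keeps the cohort's size continuum unimodal; the size-class
    label of a lesion is a threshold on its semi-major axis. The three
    semi-axes vary independently around separated means so shape and size
    decorrelate across the class.
    """
    a = np.clip(rng.normal(4.8, 0.7), 3.0, 6.6)
    b = min(np.clip(rng.normal(3.6, 0.7), 2.0, 5.4), 0.97 * a)
    c = min(np.clip(rng.normal(2.4, 0.7), 1.2, 4.2), 0.97 * b)
    return np.maximum(np.array([a, b, c]), min_axis)


def c1_size_class(semi_major: float) -> str:
    """Qualitative size label for a C1 lesion from its semi-major axis (mm)."""
    if semi_major < 3.3:
        return "small"
    if semi_major < 4.4:
        return "medium"
    return "large"


def _draw_semi_axes(
    rng: np.random.Generator, size_class: str, min_axis: float = 1.0
) -> np.ndarray:
    # the three semi-axes are drawn independently so shape (anisotropy) varies
    # independently of overall size; Gaussian draws around the class midpoint
    # keep the cohort-level size distribution smooth and unimodal
    lo, hi = SIZE_CLASSES[size_class]
    mid, sd = (lo + hi) / 2.0, (hi - lo) / 4.0
    axes = np.sort(np.clip(rng.normal(mid, sd, size=3), lo - sd, hi + sd))[::-1]
    return np.maximum(axes, min_axis)


def _semi_axes_from_major(
    rng: np.random.Generator, a: float, min_axis: float = 1.0
) -> np.ndarray:
    minor = np.sort(rng.uniform(0.8 * a, 0.92 * a, size=2))[::-1]
    return np.maximum(np.array([a, minor[0], minor[1]]), min_axis)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    return Rotation.random(rng=rng).as_matrix()


def sample_lesion_pattern(
    pattern_class: str,
    rng: np.random.Generator,
    *,
    center_mm: Sequence[float] = (30.0, 30.0, 30.0),
    patient_id: str = "p0",
    label: int = 1,
    voxel_size: Sequence[float] = (1.0, 1.0, 1.0),
    shell_ranges: dict[str, tuple[float, float]] | None = None,
    gd_ring: bool = False,
) -> dict[tuple[int, Agent], LesionObservation]:
    """Draw one lesion's observations following a pattern-class template.

    Size, exact shape and orientation are randomized; agent presence,
    persistence and focal/ring character follow the class. ``gd_ring`` makes
    a C1 lesion's Gd enhancement ring-shaped instead of focal (the cohort's
    ring-shaped share is not confined to USPIO).
    """
    if pattern_class not in PATTERN_CLASSES:
        raise ValueError(f"unknown pattern class {pattern_class!r}")
    center = np.asarray(center_mm, dtype=float)
    common = dict(patient_id=patient_id, label=label, voxel_size=voxel_size)
    out: dict[tuple[int, Agent], LesionObservation] = {}

    ranges = SHELL_RANGES if shell_ranges is None else shell_ranges

    def shell(key: str) -> float:
        # per-ring shell draw keeps hollowness a continuum across the cohort
        return float(rng.uniform(*ranges[key]))

    if pattern_class == "C1":
        axes = _draw_c1_axes(rng)
        R = _random_rotation(rng)
        if gd_ring:
            out[(0, Agent.GD)] = make_ring_mask(
                center, axes, shell("C1"), R, time_index=0, agent=Agent.GD, **common
            )
        else:
            out[(0, Agent.GD)] = make_ellipsoid_mask(
                center, axes, R, time_index=0, agent=Agent.GD, **common
            )
    elif pattern_class == "C2":
        # medium-to-large, spanning the cohort's upper size range
        axes = _semi_axes_from_major(rng, rng.uniform(*C2_SIZE_RANGE))
        R = _random_rotation(rng)
        shrink = rng.uniform(0.85, 0.95)
        jitter = rng.uniform(-1.0, 1.0, size=3)
        for t, scale, c in ((0, 1.0, center), (1, shrink, center + jitter)):
            out[(t, Agent.GD)] = make_ellipsoid_mask(
                c, axes * scale, R, time_index=t, agent=Agent.GD, **common
            )
            out[(t, Agent.USPIO)] = make_ring_mask(
                c,
                axes * scale * rng.uniform(0.62, 0.72),
                shell("C2"),
                R,
                time_index=t,
                agent=Agent.USPIO,
                **common,
            )
    else:  # C3
        axes = _semi_axes_from_major(rng, rng.uniform(*C3_SIZE_RANGE))
        R = _random_rotation(rng)
        out[(0, Agent.GD)] = make_ring_mask(
            center, axes, shell("C3_gd"), R, time_index=0, agent=Agent.GD, **common
        )
        out[(0, Agent.USPIO)] = make_ring_mask(
            center,
            axes * rng.uniform(0.95, 1.05),
            shell("C3_uspio"),
            R,
            time_index=0,
            agent=Agent.USPIO,
            **common,
        )
    return out


def _expected_counts(spec: CohortSpec) -> tuple[float, float, float]:
    """Expected (C1-lesion, severe-lesion, total) counts under the spec."""
    n_a, n_b, _ = spec.group_counts
    mean_c1_a = (spec.c1_per_patient[0] + spec.c1_per_patient[1]) / 2
    mean_c1_b = (spec.c1_per_patient_b[0] + spec.c1_per_patient_b[1]) / 2
    mean_sev = (spec.severe_per_patient[0] + spec.severe_per_patient[1]) / 2
    c1 = n_a * mean_c1_a + n_b * mean_c1_b
    severe = n_a * mean_sev
    return c1, severe, c1 + severe


def _c1_gd_ring_probability(spec: CohortSpec) -> float:
    """Rate of ring-shaped Gd enhancement among C1 lesions to hit ring_fraction.

    Severe (C2/C3) lesions always carry a ring, as do half the incidental
    USPIO co-enhancements; the remainder of the ring budget is met by
    ring-shaped Gd-only C1 lesions:
    ring_fraction · total = severe + (p_uspio/2 + q) · c1.
    """
    c1, severe, total = _expected_counts(spec)
    if c1 == 0:
        return 0.0
    q = (spec.ring_fraction * total - severe) / c1 - spec.c1_uspio_prob / 2.0
    return float(np.clip(q, 0.0, 1.0))


def sample_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a full cohort: masks per (patient, time, agent), outcomes, truth."""
    rng = np.random.default_rng(spec.seed)
    n_a, n_b, n_c = spec.group_counts
    groups = ["A"] * n_a + ["B"] * n_b + ["C"] * n_c
    rng.shuffle(groups)
    p_gd_ring = _c1_gd_ring_probability(spec)

    observations: list[LesionObservation] = []
    lesion_class: dict[tuple[str, int], str] = {}
    obs_to_lesion: dict[tuple[str, int, str, int], tuple[str, int]] = {}
    cardinalities: dict[str, np.ndarray] = {}
    group_of: dict[str, str] = {}
    uspio_only_placed = False

    for ip, group in enumerate(groups):
        pid = f"p{ip + 1:02d}"
        group_of[pid] = group
        counts = np.zeros(3, dtype=int)
        classes: list[str] = []
        if group == "A":
            n_sev = int(rng.integers(spec.severe_per_patient[0], spec.severe_per_patient[1] + 1))
            classes += [("C2", "C3")[int(rng.integers(0, 2))] for _ in range(n_sev)]
            n_c1 = int(rng.integers(spec.c1_per_patient[0], spec.c1_per_patient[1] + 1))
            classes += ["C1"] * n_c1
        elif group == "B":
            n_c1 = int(rng.integers(spec.c1_per_patient_b[0], spec.c1_per_patient_b[1] + 1))
            classes += ["C1"] * n_c1

        # jittered grid placement keeps distinct lesions from overlapping
        spacing = 40.0
        side = max(1, int(np.ceil(len(classes) ** (1.0 / 3.0))))
        for il, cls in enumerate(classes):
            gi, gj, gk = il % side, (il // side) % side, il // (side * side)
            center = (np.array([gi, gj, gk]) + 1.0) * spacing + rng.uniform(-3, 3, size=3)
            label = il + 1
            obsmap = sample_lesion_pattern(
                cls,
                rng,
                center_mm=center,
                patient_id=pid,
                label=label,
                voxel_size=spec.voxel_size,
                gd_ring=(cls == "C1" and rng.random() < p_gd_ring),
            )
            if cls == "C1":
                if spec.include_uspio_only and not uspio_only_placed and group != "C":
                    # the one USPIO-enhanced lesion with no Gd counterpart
                    ring = make_ring_mask(
                        center,
                        _draw_semi_axes(rng, "small"),
                        float(rng.uniform(*SHELL_RANGES["C1"])),
                        _random_rotation(rng),
                        spec.voxel_size,
                        patient_id=pid,
                        time_index=0,
                        agent=Agent.USPIO,
                        label=label,
                    )
                    obsmap = {(0, Agent.USPIO): ring}
                    uspio_only_placed = True
                elif rng.random() < spec.c1_uspio_prob:
                    # incidental mild USPIO co-enhancement on a C1 lesion
                    gd0 = obsmap[(0, Agent.GD)]
                    mm_center = gd0.voxel_coords.astype(float).mean(axis=0) * np.asarray(
                        spec.voxel_size
                    )
                    us_axes = _draw_semi_axes(rng, "small")
                    us_kwargs = dict(
                        patient_id=pid, time_index=0, agent=Agent.USPIO, label=label
                    )
                    if rng.random() < 0.5:
                        obsmap[(0, Agent.USPIO)] = make_ring_mask(
                            mm_center,
                            us_axes,
                            float(rng.uniform(*SHELL_RANGES["C1"])),
                            _random_rotation(rng),
                            spec.voxel_size,
                            **us_kwargs,
                        )
                    else:
                        obsmap[(0, Agent.USPIO)] = make_ellipsoid_mask(
                            mm_center,
                            us_axes,
                            _random_rotation(rng),
                            spec.voxel_size,
                            **us_kwargs,
                        )
            lesion_key = (pid, il)
            lesion_class[lesion_key] = cls
            counts[PATTERN_CLASSES.index(cls)] += 1
            for (t, agent), obs in obsmap.items():
                observations.append(obs)
                obs_to_lesion[(pid, t, agent.value, obs.label)] = lesion_key
        cardinalities[pid] = counts

    beta = np.asarray(spec.beta_true, dtype=float)
    outcomes: dict[str, tuple[float, float]] = {}
    noiseless: dict[str, float] = {}
    for pid in sorted(group_of):
        mu = float(cardinalities[pid] @ beta)
        noiseless[pid] = mu
        y = max(0.0, mu + rng.normal(0.0, spec.noise_sd))
        tll = max(0.0, 2.5 * y + abs(rng.normal(0.0, spec.noise_sd)))
        outcomes[pid] = (y, tll)

    truth = GroundTruth(
        lesion_class=lesion_class,
        obs_to_lesion=obs_to_lesion,
        cardinalities=cardinalities,
        beta_true=beta,
        noiseless_outcomes=noiseless,
        groups=group_of,
    )
    return SyntheticCohort(spec=spec, observations=observations, outcomes=outcomes, truth=truth)


def write_outcomes_csv(cohort: SyntheticCohort, path: str | Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "hypointense_m24_ml", "tll_m24_ml", "group"])
        for pid in cohort.patient_ids:
            hypo, tll = cohort.outcomes[pid]
            writer.writerow([pid, f"{hypo:.6f}", f"{tll:.6f}", cohort.truth.groups[pid]])


def write_nifti_masks(cohort: SyntheticCohort, outdir: str | Path) -> list[Path]:
    """Render observations into labeled volumes, one NIfTI per (patient, t, agent)."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_volume: dict[tuple[str, int, Agent], list[LesionObservation]] = {}
    for obs in cohort.observations:
        by_volume.setdefault((obs.patient_id, obs.time_index, obs.agent), []).append(obs)
    written = []
    vsize = cohort.spec.voxel_size
    for (pid, t, agent), obs_list in sorted(by_volume.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2].value)):
        extent = np.max([o.voxel_coords.max(axis=0) for o in obs_list], axis=0) + 2
        vol = np.zeros(tuple(int(e) for e in extent), dtype=np.int16)
        for o in obs_list:
            vol[tuple(o.voxel_coords.T)] = o.label
        affine = np.diag([*vsize, 1.0])
        img = nib.Nifti1Image(vol, affine)
        img.header.set_zooms(vsize)
        path = outdir / f"{pid}_{t}_{agent.value}.nii.gz"
        nib.save(img, str(path))
        written.append(path)
    return written
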