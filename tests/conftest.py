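import numpy as np
import pytest

from lespat.mask_io import Agent, LesionObservation, MaskVolume


def obs(coords, patient="p1", t=0, agent=Agent.GD, label=1, voxel_size=(1.0, 1.0, 1.0)):
    """Shorthand LesionObservation builder used across the suite."""
    return LesionObservation(
        patient_id=patient,
        time_index=t,
        agent=agent,
        label=label,
        voxel_coords=np.asarray(coords, dtype=np.int64),
        voxel_size=voxel_size,
    )


def box_coords(ni, nj, nk, offset=(0, 0, 0)):
    """All voxel indices of an ni×nj×nk box."""
    oi, oj, ok = offset
    return [(i + oi, j + oj, k + ok) for i in range(ni) for j in range(nj) for k in range(nk)]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_blobs():
    """3 well-separated Gaussian blobs (centers >= 10 sigma apart) + labels."""
    rng = np.random.default_rng(0)
    centers = np.array([[0.0, 0.0], [15.0, 0.0], [0.0, 15.0]])
    X = np.vstack([rng.normal(size=(25, 2)) + c for c in centers])
    y = np.repeat([0, 1, 2], 25)
    return X, y


@pytest.fixture
def volume_factory():
    def make(array, patient="p1", t=0, agent=Agent.GD, voxel_size=(1.0, 1.0, 1.0)):
        return MaskVolume(
            voxels=np.asarray(array, dtype=np.int32),
            voxel_size=voxel_size,
            patient_id=patient,
            time_index=t,
            agent=agent,
        )

    return make


# the 24 proper rotations of the cube, as integer matrices
def _proper_grid_rotations():
    import itertools

    mats = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product([1, -1], repeat=3):
            M = np.zeros((3, 3), dtype=int)
            for row, col in enumerate(perm):
                M[row, col] = signs[row]
            if round(np.linalg.det(M)) == 1:
                mats.append(M)
    return mats


GRID_ROTATIONS = _proper_grid_rotations()
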