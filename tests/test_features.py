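import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lespat.features import (
    assemble_trajectory_vector,
    binarize_hollowness,
    build_feature_matrix,
    centered_coordinate_matrix,
    covariance_eigenvalues,
    feature_columns,
    hollowness_index,
    shape_features,
)
from lespat.mask_io import Agent, LesionTrajectory
from lespat.synthetic import make_ellipsoid_mask

from conftest import GRID_ROTATIONS, box_coords, obs


class TestCenteredCoordinateMatrix:
    def test_single_voxel_is_zero_row(self):
        M = centered_coordinate_matrix(obs([(3, 4, 5)]))
        assert M.shape == (1, 3)
        assert np.allclose(M, 0)

    def test_line_of_voxels(self):
        M = centered_coordinate_matrix(obs([(i, 2, 7) for i in range(5)]))
        assert np.allclose(M[:, 0], [-2, -1, 0, 1, 2])
        assert np.allclose(M[:, 1:], 0)

    def test_anisotropic_voxels_scaled_to_mm(self):
        M = centered_coordinate_matrix(obs([(0, 0, 0), (0, 0, 1)], voxel_size=(1, 1, 3)))
        assert np.allclose(M[:, 2], [-1.5, 1.5])

    def test_columns_centered(self, rng):
        coords = rng.integers(0, 20, size=(40, 3))
        coords = np.unique(coords, axis=0)
        M = centered_coordinate_matrix(obs(coords))
        assert np.allclose(M.sum(axis=0), 0, atol=1e-9)


class TestCovarianceEigenvalues:
    def test_single_point(self):
        assert covariance_eigenvalues(np.zeros((1, 3))) == (0.0, 0.0, 0.0)

    def test_box_closed_form(self):
        # variance of 0..n-1 at unit spacing is (n^2 - 1) / 12
        M = centered_coordinate_matrix(obs(box_coords(5, 3, 1)))
        l1, l2, l3 = covariance_eigenvalues(M)
        assert l1 == pytest.approx((25 - 1) / 12)
        assert l2 == pytest.approx((9 - 1) / 12)
        assert l3 == pytest.approx(0.0, abs=1e-12)

    def test_sorted_descending_nonnegative(self, rng):
        coords = np.unique(rng.integers(0, 15, size=(60, 3)), axis=0)
        l1, l2, l3 = covariance_eigenvalues(centered_coordinate_matrix(obs(coords)))
        assert l1 >= l2 >= l3 >= 0

    @pytest.mark.parametrize("R", GRID_ROTATIONS[::5])
    def test_grid_rotation_invariance(self, R, rng):
        coords = np.unique(rng.integers(-8, 8, size=(50, 3)), axis=0)
        base = covariance_eigenvalues(centered_coordinate_matrix(obs(coords + 8)))
        rotated = coords @ R.T
        rot = covariance_eigenvalues(centered_coordinate_matrix(obs(rotated - rotated.min(axis=0))))
        assert np.allclose(base, rot, atol=1e-9)

    def test_isotropic_scaling_quadratic(self):
        # doubled grid spacing realized via voxel_size: eigenvalues scale by s^2
        coords = box_coords(4, 3, 2)
        e1 = covariance_eigenvalues(centered_coordinate_matrix(obs(coords)))
        e2 = covariance_eigenvalues(
            centered_coordinate_matrix(obs(coords, voxel_size=(2.0, 2.0, 2.0)))
        )
        assert np.allclose(np.array(e2), 4.0 * np.array(e1))


class TestEllipsoidOracle:
    def test_solid_ellipsoid_matches_continuous_form(self):
        # continuous uniform solid ellipsoid has coordinate variances (a^2/5, b^2/5, c^2/5)
        a, b, c = 12.0, 8.0, 5.0
        lesion = make_ellipsoid_mask((20, 20, 20), (a, b, c), voxel_size=(1, 1, 1))
        l1, l2, l3 = covariance_eigenvalues(centered_coordinate_matrix(lesion))
        expected = np.array([a * a, b * b, c * c]) / 5.0
        assert np.allclose([l1, l2, l3], expected, rtol=0.05)

    def test_rotated_ellipsoid_same_eigenvalues(self):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", [30, 45, 60], degrees=True).as_matrix()
        plain = make_ellipsoid_mask((20, 20, 20), (12, 8, 6))
        rot = make_ellipsoid_mask((20, 20, 20), (12, 8, 6), rotation=R)
        e0 = covariance_eigenvalues(centered_coordinate_matrix(plain))
        e1 = covariance_eigenvalues(centered_coordinate_matrix(rot))
        assert np.allclose(e0, e1, rtol=0.05)

    def test_axis_ratio(self):
        lesion = make_ellipsoid_mask((20, 20, 20), (6, 3, 3))
        l1, l2, _ = covariance_eigenvalues(centered_coordinate_matrix(lesion))
        assert l1 / l2 == pytest.approx(4.0, rel=0.1)


class TestHollowness:
    def test_solid_square(self):
        assert hollowness_index(obs(box_coords(3, 3, 1))) == 1.0

    def test_square_with_center_hole(self):
        coords = [c for c in box_coords(5, 5, 1) if c != (2, 2, 0)]
        assert hollowness_index(obs(coords)) == pytest.approx(24 / 25)

    def test_two_slices_one_ring(self):
        solid = box_coords(3, 3, 1)  # 9 voxels, slice k=0
        ring = [c for c in box_coords(3, 3, 1, offset=(0, 0, 1)) if c != (1, 1, 1)]  # 8 of 9
        assert hollowness_index(obs(solid + ring)) == pytest.approx(17 / 18)

    def test_ring_less_hollow_when_filled(self):
        ring = [c for c in box_coords(7, 7, 1) if c not in box_coords(3, 3, 1, offset=(2, 2, 0))]
        h = hollowness_index(obs(ring))
        assert h < 1.0
        filled = box_coords(7, 7, 1)
        assert hollowness_index(obs(filled)) == 1.0

    def test_3d_fill_option(self):
        # hollow cube: 3D fill recovers the interior, per-slice fill also does
        cube = box_coords(5, 5, 5)
        hollow = [c for c in cube if c != (2, 2, 2)]
        assert hollowness_index(obs(hollow), fill_3d=True) == pytest.approx(124 / 125)

    @given(st.integers(min_value=3, max_value=7))
    @settings(max_examples=10, deadline=None)
    def test_hollowness_in_unit_interval(self, n):
        coords = [c for c in box_coords(n, n, 1) if c != (1, 1, 0)]
        h = hollowness_index(obs(coords))
        assert 0 < h <= 1


class TestBinarizeHollowness:
    @pytest.mark.parametrize("h,expected", [(1.0, 1), (0.96, 1), (0.5, 1), (0.3, 0), (0.49, 0)])
    def test_rounding(self, h, expected):
        assert binarize_hollowness(h) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            binarize_hollowness(0.0)


class TestShapeFeatures:
    def test_tensor_on_filled_ring(self):
        ring = [c for c in box_coords(7, 7, 1) if c not in box_coords(3, 3, 1, offset=(2, 2, 0))]
        filled = box_coords(7, 7, 1)
        f_ring = shape_features(obs(ring), tensor_on_filled=True)
        f_filled = shape_features(obs(filled))
        assert f_ring.eigenvalues == pytest.approx(f_filled.eigenvalues)
        assert f_ring.hollowness < 1.0 == f_filled.hollowness

    def test_unfilled_option_differs(self):
        ring = [c for c in box_coords(7, 7, 1) if c not in box_coords(3, 3, 1, offset=(2, 2, 0))]
        on = shape_features(obs(ring), tensor_on_filled=True)
        off = shape_features(obs(ring), tensor_on_filled=False)
        # removing interior mass increases spread relative to the filled body
        assert off.eigenvalues[0] > on.eigenvalues[0]

    def test_volume_in_mm3(self):
        f = shape_features(obs(box_coords(3, 3, 3), voxel_size=(1, 1, 3)))
        assert f.volume == pytest.approx(27 * 3.0)


def _trajectory(obsmap, patient="p1", tid="p1_t"):
    return LesionTrajectory(patient_id=patient, trajectory_id=tid, observations=obsmap)


class TestAssembleTrajectoryVector:
    def test_zero_fill_for_absent_blocks(self):
        o = obs(box_coords(3, 3, 2))
        v = assemble_trajectory_vector(_trajectory({(0, Agent.GD): o}), 2)
        assert v.shape == (16,)
        assert np.any(v[:4] != 0)
        assert np.all(v[4:] == 0)

    def test_full_trajectory_no_zero_blocks(self):
        obsmap = {
            (t, a): obs(box_coords(3, 3, 2), t=t, agent=a)
            for t in (0, 1)
            for a in (Agent.GD, Agent.USPIO)
        }
        v = assemble_trajectory_vector(_trajectory(obsmap), 2)
        blocks = v.reshape(4, 4)
        assert np.all(np.any(blocks != 0, axis=1))

    def test_volume_mode(self):
        o = obs(box_coords(3, 3, 3))
        v = assemble_trajectory_vector(_trajectory({(0, Agent.GD): o}), 2, mode="volume")
        assert v.shape == (4,)
        assert v[0] == pytest.approx(27.0)
        assert np.all(v[1:] == 0)

    def test_binary_hollow_mode(self):
        ring = [c for c in box_coords(4, 4, 1) if c not in [(1, 1, 0), (2, 1, 0), (1, 2, 0), (2, 2, 0)]]
        o = obs(ring)
        v = assemble_trajectory_vector(
            _trajectory({(0, Agent.GD): o}), 2, hollow_mode="binary"
        )
        assert v[3] in (0.0, 1.0)

    def test_time_index_out_of_range(self):
        o = obs(box_coords(2, 2, 1), t=3)
        with pytest.raises(ValueError, match="n_timepoints"):
            assemble_trajectory_vector(_trajectory({(3, Agent.GD): o}), 2)


class TestBuildFeatureMatrix:
    def _trajs(self, n=4):
        out = []
        for i in range(n):
            o = obs(box_coords(3 + i, 3, 2), label=i + 1)
            out.append(_trajectory({(0, Agent.GD): o}, tid=f"p1_{i}"))
        return out

    def test_identical_vectors_without_standardize(self):
        t1 = _trajectory({(0, Agent.GD): obs(box_coords(3, 3, 2))}, tid="a")
        t2 = _trajectory({(0, Agent.GD): obs(box_coords(3, 3, 2))}, tid="b")
        fm = build_feature_matrix([t1, t2], 2, standardize=False)
        assert np.array_equal(fm.values[0], fm.values[1])

    def test_standardized_columns(self):
        fm = build_feature_matrix(self._trajs(), 2, standardize=True)
        nonconst = ~fm.constant_columns()
        assert np.allclose(fm.values[:, nonconst].mean(axis=0), 0, atol=1e-9)
        assert np.allclose(fm.values[:, nonconst].std(axis=0), 1, atol=1e-9)

    def test_constant_columns_flagged_zero(self):
        fm = build_feature_matrix(self._trajs(), 2, standardize=True)
        const = fm.constant_columns()
        assert const.any()  # USPIO columns are all absent here
        assert np.all(fm.values[:, const] == 0)

    def test_insufficient_rows(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_feature_matrix(self._trajs(1), 2)

    def test_tsv_roundtrip(self, tmp_path):
        from lespat.features import FeatureMatrix

        fm = build_feature_matrix(self._trajs(), 2, standardize=True)
        path = tmp_path / "features.tsv"
        fm.to_tsv(path)
        back = FeatureMatrix.from_tsv(path)
        assert back.row_ids == fm.row_ids
        assert np.allclose(back.values, fm.values)
        assert back.standardized
        assert np.allclose(back.column_means, fm.column_means)

    def test_column_layout(self):
        cols = feature_columns(2)
        assert cols[0] == "gd_t0_l1"
        assert cols[8] == "uspio_t0_l1"
        assert len(cols) == 16


class TestRotationInvarianceEndToEnd:
    def test_all_grid_rotations_leave_vector_unchanged(self):
        # convex mask: hole-free in every orientation, so H is invariant too
        coords = make_ellipsoid_mask((8, 8, 8), (6, 4, 3)).voxel_coords
        o = obs(coords)
        base = assemble_trajectory_vector(_trajectory({(0, Agent.GD): o}), 2)
        for R in GRID_ROTATIONS:
            rc = coords @ R.T
            rc = rc - rc.min(axis=0)
            v = assemble_trajectory_vector(_trajectory({(0, Agent.GD): obs(rc)}), 2)
            assert np.allclose(v, base, atol=1e-9)
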