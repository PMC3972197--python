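import numpy as np
import pytest

from lespat.features import (
    binarize_hollowness,
    centered_coordinate_matrix,
    covariance_eigenvalues,
    hollowness_index,
)
from lespat.mask_io import Agent
from lespat.synthetic import (
    CohortSpec,
    PATTERN_CLASSES,
    make_ellipsoid_mask,
    make_ring_mask,
    sample_cohort,
    sample_lesion_pattern,
    write_nifti_masks,
    write_outcomes_csv,
)


class TestMakeEllipsoidMask:
    def test_sphere_volume(self):
        lesion = make_ellipsoid_mask((10, 10, 10), (5, 5, 5))
        assert lesion.m == pytest.approx(4 / 3 * np.pi * 125, rel=0.05)

    def test_eigenvalue_ratio(self):
        lesion = make_ellipsoid_mask((15, 15, 15), (6, 3, 3))
        l1, l2, _ = covariance_eigenvalues(centered_coordinate_matrix(lesion))
        assert l1 / l2 == pytest.approx(4.0, rel=0.12)

    def test_rotation_leaves_eigenvalues(self, rng):
        from scipy.spatial.transform import Rotation

        R = Rotation.random(rng=rng).as_matrix()
        a = make_ellipsoid_mask((15, 15, 15), (10, 7, 5))
        b = make_ellipsoid_mask((15, 15, 15), (10, 7, 5), rotation=R)
        ea = covariance_eigenvalues(centered_coordinate_matrix(a))
        eb = covariance_eigenvalues(centered_coordinate_matrix(b))
        assert np.allclose(ea, eb, rtol=0.05)

    def test_clipping_warns(self):
        with pytest.warns(UserWarning, match="clipped"):
            make_ellipsoid_mask((1, 1, 1), (4, 4, 4), shape=(3, 3, 3))

    def test_subvoxel_axes_rejected(self):
        with pytest.raises(ValueError):
            make_ellipsoid_mask((5, 5, 5), (0.4, 0.4, 0.4))


class TestMakeRingMask:
    def test_hollowness_matches_shell_cube(self):
        # H = 1 - f^3 for a concentric shell at fine resolution
        f = 0.6
        ring = make_ring_mask((15, 15, 15), (12, 12, 12), shell_fraction=f, voxel_size=(0.5, 0.5, 0.5))
        assert hollowness_index(ring) == pytest.approx(1 - f**3, abs=0.02)

    def test_thin_shell_limit(self):
        ring = make_ring_mask((10, 10, 10), (6, 6, 6), shell_fraction=0.15)
        assert hollowness_index(ring) > 0.99

    def test_thick_ring_binarizes_to_zero(self):
        ring = make_ring_mask((12, 12, 12), (10, 10, 10), shell_fraction=0.85, voxel_size=(0.5, 0.5, 0.5))
        h = hollowness_index(ring)
        assert h < 0.5
        assert binarize_hollowness(h) == 0

    def test_coarse_fallback_removes_interior_voxel(self):
        ring = make_ring_mask((5, 5, 5), (1.5, 1.5, 1.5), shell_fraction=0.1)
        assert hollowness_index(ring) < 1.0

    def test_shell_fraction_validated(self):
        with pytest.raises(ValueError):
            make_ring_mask((5, 5, 5), (3, 3, 3), shell_fraction=1.2)


class TestSampleLesionPattern:
    def test_c1_template(self, rng):
        obsmap = sample_lesion_pattern("C1", rng)
        assert set(a for (_, a) in obsmap) == {Agent.GD}
        assert set(t for (t, _) in obsmap) == {0}

    def test_c2_template(self, rng):
        obsmap = sample_lesion_pattern("C2", rng)
        assert set(obsmap) == {(t, a) for t in (0, 1) for a in (Agent.GD, Agent.USPIO)}
        assert hollowness_index(obsmap[(0, Agent.GD)]) == 1.0
        assert hollowness_index(obsmap[(0, Agent.USPIO)]) < 1.0

    def test_c3_template(self, rng):
        obsmap = sample_lesion_pattern("C3", rng)
        assert set(obsmap) == {(0, Agent.GD), (0, Agent.USPIO)}
        assert hollowness_index(obsmap[(0, Agent.GD)]) < 1.0
        assert hollowness_index(obsmap[(0, Agent.USPIO)]) < 1.0

    def test_templates_reidentifiable(self, rng):
        # class membership is recoverable from agent presence/persistence rules
        for _ in range(60):
            cls = PATTERN_CLASSES[rng.integers(0, 3)]
            obsmap = sample_lesion_pattern(cls, rng)
            has_uspio = any(a == Agent.USPIO for (_, a) in obsmap)
            has_t1 = any(t == 1 for (t, _) in obsmap)
            if not has_uspio:
                inferred = "C1"
            elif has_t1:
                inferred = "C2"
            else:
                inferred = "C3"
            assert inferred == cls

    def test_unknown_class(self, rng):
        with pytest.raises(ValueError):
            sample_lesion_pattern("C9", rng)


@pytest.fixture(scope="module")
def cohort():
    return sample_cohort(CohortSpec(seed=7))


class TestSampleCohort:

    def test_group_counts(self, cohort):
        counts = {g: list(cohort.truth.groups.values()).count(g) for g in "ABC"}
        assert counts == {"A": 5, "B": 13, "C": 7}

    def test_seven_group_c_patients_have_no_lesions(self, cohort):
        group_c = [p for p, g in cohort.truth.groups.items() if g == "C"]
        assert len(group_c) == 7
        for pid in group_c:
            assert cohort.observations_for(pid) == []

    def test_group_a_has_severe_pattern(self, cohort):
        for pid, g in cohort.truth.groups.items():
            card = cohort.truth.cardinalities[pid]
            if g == "A":
                assert card[1] + card[2] >= 1
            elif g == "B":
                assert card[1] + card[2] == 0 and card[0] >= 1

    def test_lesion_scale_matches_study(self, cohort):
        gd = {
            cohort.truth.obs_to_lesion[(o.patient_id, o.time_index, o.agent.value, o.label)]
            for o in cohort.observations
            if o.agent == Agent.GD
        }
        uspio = {
            cohort.truth.obs_to_lesion[(o.patient_id, o.time_index, o.agent.value, o.label)]
            for o in cohort.observations
            if o.agent == Agent.USPIO
        }
        assert 103 * 0.7 <= len(gd) <= 103 * 1.3
        assert 24 * 0.7 <= len(uspio) <= 24 * 1.3

    def test_ring_share_near_quarter(self, cohort):
        n_ring_lesions = len(
            {
                cohort.truth.obs_to_lesion[(o.patient_id, o.time_index, o.agent.value, o.label)]
                for o in cohort.observations
                if hollowness_index(o) < 0.995
            }
        )
        total = len(cohort.truth.lesion_class)
        assert 0.12 <= n_ring_lesions / total <= 0.40

    def test_outcomes_linear_in_truth(self, cohort):
        spec = cohort.spec
        beta = np.asarray(spec.beta_true)
        for pid, (y, _) in cohort.outcomes.items():
            mu = cohort.truth.cardinalities[pid] @ beta
            assert abs(y - mu) <= 5 * spec.noise_sd or (mu == 0 and y >= 0)

    def test_noiseless_outcomes_exact(self):
        cohort = sample_cohort(CohortSpec(seed=3, noise_sd=0.0))
        for pid, (y, _) in cohort.outcomes.items():
            assert y == pytest.approx(cohort.truth.noiseless_outcomes[pid])

    def test_determinism(self):
        a = sample_cohort(CohortSpec(seed=11))
        b = sample_cohort(CohortSpec(seed=11))
        assert a.outcomes == b.outcomes
        assert len(a.observations) == len(b.observations)
        for oa, ob in zip(a.observations, b.observations):
            assert np.array_equal(oa.voxel_coords, ob.voxel_coords)

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(group_counts=(5, 13, 6))
        with pytest.raises(ValueError):
            CohortSpec(group_counts=(5, 13, 7), severe_per_patient=(0, 0))

    def test_uspio_only_lesion_flag(self):
        cohort = sample_cohort(CohortSpec(seed=1, include_uspio_only=True))
        uspio_only = set()
        gd_lesions = set()
        for o in cohort.observations:
            key = cohort.truth.obs_to_lesion[(o.patient_id, o.time_index, o.agent.value, o.label)]
            if o.agent == Agent.USPIO:
                uspio_only.add(key)
            else:
                gd_lesions.add(key)
        assert len(uspio_only - gd_lesions) == 1


class TestCohortIO:
    def test_outcomes_csv(self, tmp_path):
        cohort = sample_cohort(CohortSpec(seed=2))
        path = tmp_path / "outcomes.csv"
        write_outcomes_csv(cohort, path)
        import csv

        rows = list(csv.DictReader(open(path)))
        assert len(rows) == 25
        assert {"patient_id", "hypointense_m24_ml", "tll_m24_ml", "group"} <= set(rows[0])

    def test_nifti_roundtrip(self, tmp_path):
        from lespat.mask_io import extract_observations, load_mask_volume

        spec = CohortSpec(
            seed=4, n_patients=3, group_counts=(1, 1, 1),
            c1_per_patient=(1, 2), c1_per_patient_b=(1, 2), severe_per_patient=(1, 1),
        )
        cohort = sample_cohort(spec)
        paths = write_nifti_masks(cohort, tmp_path)
        assert paths
        total = 0
        for path in paths:
            pid, t, agent = path.name.replace(".nii.gz", "").rsplit("_", 2)
            vol = load_mask_volume(path, pid, int(t), Agent(agent))
            total += sum(o.m for o in extract_observations(vol))
        assert total == sum(o.m for o in cohort.observations)
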