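"""ICP, non-rigid template warping, and cohort correspondence."""

import warnings

import numpy as np
import pytest
from scipy.spatial import cKDTree

from vcohort import (GeneratorConfig, GeometryError, Surface,
                     align_calcifications, align_cohort, make_cohort,
                     nonrigid_register, resample, rigid_icp)
from vcohort.registration import RigidTransform


def _random_cloud(rng, n=120, extent=30.0):
    return rng.uniform(-extent / 2, extent / 2, size=(n, 3))


def _rotation(axis, angle):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


class TestRigidICP:
    def test_cloud_vs_itself_is_identity(self, rng):
        pts = _random_cloud(rng)
        surf = Surface("a", "wall", pts)
        T = rigid_icp(surf, surf)
        assert np.allclose(T.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(T.translation, 0, atol=1e-9)
        tree = cKDTree(pts)
        assert tree.query(T.apply(pts))[0].max() < 1e-9

    def test_recovers_planted_rotation_translation(self, rng):
        """30 degrees about z plus a (5, -2, 1) mm shift is inverted."""
        pts = _random_cloud(rng)
        R = _rotation([0, 0, 1], np.radians(30))
        moved = pts @ R.T + np.array([5.0, -2.0, 1.0])
        T = rigid_icp(Surface("m", "wall", moved), Surface("f", "wall", pts))
        rms = np.sqrt(((T.apply(moved) - pts) ** 2).sum(axis=1).mean())
        assert rms < 0.01
        assert np.allclose(T.rotation, R.T, atol=1e-6)

    def test_recovers_planted_scale(self, rng):
        pts = _random_cloud(rng)
        scaled = pts * 1.2
        T = rigid_icp(Surface("m", "wall", scaled), Surface("f", "wall", pts),
                      with_scale=True)
        assert abs(T.scale - 1 / 1.2) < 0.01 / 1.2

    def test_rotation_is_orthonormal_with_unit_det(self, rng):
        for _ in range(5):
            pts = _random_cloud(rng)
            R = _rotation(rng.normal(size=3), rng.uniform(0, np.pi / 3))
            moved = pts @ R.T + rng.normal(0, 3, 3)
            T = rigid_icp(Surface("m", "wall", moved),
                          Surface("f", "wall", pts))
            assert np.allclose(T.rotation @ T.rotation.T, np.eye(3),
                               atol=1e-10)
            assert abs(np.linalg.det(T.rotation) - 1) < 1e-8

    def test_coplanar_cloud_raises(self, rng):
        flat = np.c_[rng.random((20, 2)), np.zeros(20)]
        with pytest.raises(GeometryError):
            rigid_icp(Surface("m", "wall", flat),
                      Surface("f", "wall", _random_cloud(rng)))

    def test_determinant_invariant_on_transform(self):
        with pytest.raises(ValueError):
            RigidTransform(-np.eye(3), np.zeros(3))


def _sphere(n=400, radius=20.0, seed=0):
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    return u * radius


class TestNonrigidRegister:
    def test_identical_template_and_target_no_displacement(self):
        surf = Surface("a", "wall", _sphere())
        out = nonrigid_register(surf, surf)
        assert np.abs(out.points - surf.points).max() < 1e-9

    def test_dilated_sphere_residual_under_two_percent(self):
        radius = 20.0
        template = Surface("t", "wall", _sphere(radius=radius))
        target = Surface("g", "wall", _sphere(radius=1.1 * radius, seed=1))
        out = nonrigid_register(template, target, n_iter=10)
        residual = np.abs(np.linalg.norm(out.points, axis=1) - 1.1 * radius)
        assert residual.mean() < 0.02 * radius

    def test_huge_bandwidth_gives_pure_translation(self):
        """Without annealing, a very wide kernel averages the field away."""
        template = Surface("t", "wall", _sphere())
        target = Surface("g", "wall", _sphere(seed=2) + np.array([4.0, 0, 0]))
        out = nonrigid_register(template, target, smoothing_mm=1e5,
                                n_iter=1, anneal=False)
        disp = out.points - template.points
        assert np.abs(disp - disp.mean(axis=0)).max() < 1e-6

    def test_nonpositive_smoothing_raises(self):
        surf = Surface("a", "wall", _sphere())
        with pytest.raises(ValueError):
            nonrigid_register(surf, surf, smoothing_mm=0.0)


class TestAlignCohort:
    def test_identical_shapes_under_rigid_motions(self, rng):
        """Identical anatomy in arbitrary poses collapses to equal rows."""
        base = _sphere(300, radius=15.0) * np.array([1.0, 0.8, 1.4])
        base[:, 2] += 0.1 * base[:, 0] ** 2 / 15  # break symmetry
        surfaces = []
        for i in range(3):
            R = _rotation(rng.normal(size=3), rng.uniform(0, np.pi))
            t = rng.uniform(-20, 20, 3)
            surfaces.append(Surface(f"s{i}", "wall", base @ R.T + t))
        cohort = align_cohort(surfaces, reference_id="s0")
        assert cohort.iterations_to_mean_convergence <= 2
        spread = cohort.X.max(axis=0) - cohort.X.min(axis=0)
        assert spread.max() < 0.01

    def test_fewer_than_three_subjects_raises(self, rng):
        surfaces = [Surface(f"s{i}", "wall", _random_cloud(rng))
                    for i in range(2)]
        with pytest.raises(ValueError):
            align_cohort(surfaces, reference_id="s0")

    def test_mixed_labels_raise(self, rng):
        surfaces = [Surface("a", "wall", _random_cloud(rng)),
                    Surface("b", "calcification", _random_cloud(rng)),
                    Surface("c", "wall", _random_cloud(rng))]
        with pytest.raises(ValueError, match="mixed"):
            align_cohort(surfaces, reference_id="a")

    def test_equivariance_under_common_rigid_motion(self):
        """Co-rotating every input leaves the cohort matrix unchanged."""
        cfg = GeneratorConfig(n_patients=6, wall_points=320, calc_points=200,
                              seed=3, rigid_motion=False)
        samples, _ = make_cohort(cfg)
        walls = [s.wall for s in samples]
        R = _rotation([1, 2, 0.5], 1.1)
        t = np.array([8.0, -3.0, 12.0])
        moved = [s.with_points(s.points @ R.T + t) for s in walls]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = align_cohort(walls, reference_id=walls[0].patient_id,
                             max_mean_iter=3)
            b = align_cohort(moved, reference_id=walls[0].patient_id,
                             max_mean_iter=3)
        assert np.abs(a.X - b.X).max() < 0.01

    def test_mean_realignment_does_not_worsen_fit(self):
        """Re-aligning to the mean keeps the registration residual in check.

        The residual is the mean closest-point distance between each
        corresponded row and its aligned subject cloud; iterating against
        the mean shape must not degrade it (small fluctuation allowed for
        the correspondence limit cycle).
        """
        cfg = GeneratorConfig(n_patients=6, wall_points=320, calc_points=200,
                              seed=9)
        samples, _ = make_cohort(cfg)
        walls = [s.wall for s in samples]

        def residual(cohort):
            c = cohort.template.centroid()
            per_subject = []
            for i, s in enumerate(walls):
                T = cohort.transforms[i]
                aligned = (T.apply(s.points) - c) / T.scale + c
                per_subject.append(
                    cKDTree(aligned).query(cohort.row_points(i))[0].mean())
            return np.mean(per_subject)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            one = align_cohort(walls, reference_id=walls[0].patient_id,
                               max_mean_iter=1)
            more = align_cohort(walls, reference_id=walls[0].patient_id,
                                max_mean_iter=5)
        assert residual(more) <= residual(one) + 0.05


class TestAlignCalcifications:
    def test_comoved_plaques_need_no_extra_rotation(self, aligned_wall,
                                                    aligned_calc):
        """Calcifications rigidly co-moved with their walls keep rotation 0."""
        assert aligned_calc.axis_rotation_indices.count(0) >= \
            0.8 * len(aligned_calc.axis_rotation_indices)

    def test_planted_120_degree_rotation_is_recovered(self, small_cohort):
        samples, _ = small_cohort
        cfg_samples = samples[:5]
        walls = [resample(s.wall, 350, seed=i)
                 for i, s in enumerate(cfg_samples)]
        calcs = [resample(s.calcification, 250, seed=50 + i)
                 for i, s in enumerate(cfg_samples)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wc = align_cohort(walls, max_mean_iter=2)
            ref = align_calcifications(calcs, wc)
            # rotate one non-reference subject's plaques 120 degrees about
            # its own root axis (the wall tube direction in its frame);
            # rotating the reference would rotate the template itself
            j = next(i for i, pid in enumerate(wc.patient_ids)
                     if pid != wc.reference_id)
            wall_pts = walls[j].points
            c = wall_pts.mean(axis=0)
            axis = np.linalg.svd(wall_pts - c, full_matrices=False)[2][0]
            R = _rotation(axis, 2 * np.pi / 3)
            rotated = calcs[j].with_points((calcs[j].points - c) @ R.T + c)
            calcs2 = list(calcs)
            calcs2[j] = rotated
            out = align_calcifications(calcs2, wc)
        base = ref.axis_rotation_indices[j]
        assert out.axis_rotation_indices[j] != base

    def test_subject_mismatch_raises(self, aligned_wall, small_cohort):
        samples, _ = small_cohort
        calcs = [resample(s.calcification, 250, seed=i)
                 for i, s in enumerate(samples[:5])]
        with pytest.raises(ValueError, match="match"):
            align_calcifications(calcs, aligned_wall)
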