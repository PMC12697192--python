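"""Rigid superposition, RSA quality metrics, and ICP model fitting."""

import numpy as np
import pytest
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from ctrsa import (
    CN_THRESHOLD,
    ME_THRESHOLD,
    PointSet,
    RigidTransform,
    condition_number,
    fit_model_pose,
    fit_rigid,
    mean_error,
)
from ctrsa.registration import CN_CAP, DegenerateFitError


def _cloud(rng, n=8, scale=30.0):
    return PointSet(rng.normal(scale=scale, size=(n, 3)))


def brute_force_rigid(src, dst):
    """Independent oracle: direct least-squares over rotation-vector and
    translation parameters from several starts."""
    best = None
    for k in range(6):
        rot0 = Rotation.random(random_state=k).as_rotvec()
        x0 = np.concatenate([rot0, dst.mean(axis=0) - src.mean(axis=0)])

        def resid(x):
            R = Rotation.from_rotvec(x[:3]).as_matrix()
            return ((src @ R.T + x[3:]) - dst).ravel()

        sol = least_squares(resid, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if best is None or sol.cost < best.cost:
            best = sol
    R = Rotation.from_rotvec(best.x[:3]).as_matrix()
    return RigidTransform(R, best.x[3:])


class TestRigidTransform:
    def test_compose_inverse_roundtrip(self, rng):
        a = RigidTransform.random(rng)
        b = RigidTransform.random(rng)
        p = rng.normal(size=(10, 3))
        np.testing.assert_allclose(a.compose(b).apply(p), a.apply(b.apply(p)), atol=1e-9)
        ident = a.compose(a.inverse())
        assert ident.almost_equal(RigidTransform.identity(), tol=1e-9)

    def test_reflection_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([-1.0, 1.0, 1.0]), np.zeros(3))

    def test_json_roundtrip(self, rng):
        t = RigidTransform.random(rng)
        t2 = RigidTransform.from_dict(t.to_dict())
        assert t.almost_equal(t2, tol=1e-12)


class TestFitRigid:
    def test_identity_when_dst_equals_src(self, rng):
        ps = _cloud(rng)
        res = fit_rigid(ps, ps)
        assert res.transform.almost_equal(RigidTransform.identity(), tol=1e-9)
        assert res.mean_error == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation(self, rng):
        ps = _cloud(rng)
        dst = PointSet(ps.coords + [1.0, 2.0, 3.0], ps.labels)
        res = fit_rigid(ps, dst)
        np.testing.assert_allclose(res.transform.translation, [1, 2, 3], atol=1e-9)
        np.testing.assert_allclose(res.transform.rotation, np.eye(3), atol=1e-9)

    def test_recovers_random_transform(self, rng):
        for _ in range(20):
            ps = _cloud(rng, n=int(rng.integers(4, 12)))
            truth = RigidTransform.random(rng, 180.0, 100.0)
            dst = truth.apply_pointset(ps)
            res = fit_rigid(ps, dst)
            assert res.transform.almost_equal(truth, tol=1e-9)
            assert res.mean_error < 1e-9

    def test_label_matching_permutation_invariant(self, rng):
        ps = _cloud(rng, n=6)
        truth = RigidTransform.random(rng)
        dst = truth.apply_pointset(ps)
        perm = rng.permutation(6)
        shuffled = PointSet(dst.coords[perm], dst.labels[perm])
        res = fit_rigid(ps, shuffled)
        assert res.transform.almost_equal(truth, tol=1e-9)

    def test_equivariance_under_pre_post_transforms(self, rng):
        src = _cloud(rng, n=7)
        noisy_dst = PointSet(src.coords + rng.normal(scale=0.2, size=(7, 3)), src.labels)
        base = fit_rigid(src, noisy_dst)
        g = RigidTransform.random(rng)
        res = fit_rigid(src, g.apply_pointset(noisy_dst))
        assert res.transform.almost_equal(g.compose(base.transform), tol=1e-8)
        np.testing.assert_allclose(res.residuals, base.residuals, atol=1e-9)

    def test_matches_brute_force_oracle_on_small_sets(self, rng):
        for n in (4, 5, 6):
            for _ in range(4):
                src = _cloud(rng, n=n)
                dst = PointSet(
                    RigidTransform.random(rng).apply(src.coords)
                    + rng.normal(scale=0.3, size=(n, 3)),
                    src.labels,
                )
                ours = fit_rigid(src, dst).transform
                oracle = brute_force_rigid(src.coords, dst.coords)
                assert ours.almost_equal(oracle, tol=1e-6)

    def test_too_few_or_collinear_points_raise(self, rng):
        two = PointSet(np.array([[0.0, 0, 0], [1, 0, 0]]))
        with pytest.raises(DegenerateFitError):
            fit_rigid(two, two)
        line = PointSet(np.outer(np.arange(5.0), [1.0, 2.0, 3.0]))
        with pytest.raises(DegenerateFitError):
            fit_rigid(line, line)


class TestMeanError:
    def test_zero_residuals_pass_gate(self):
        assert mean_error(np.zeros(5)) == 0.0

    def test_empty_residuals_raise(self):
        with pytest.raises(ValueError):
            mean_error(np.array([]))

    def test_displaced_marker_matches_superposition_oracle(self, rng):
        """One bead moved by a known delta among stable beads: the RMS
        residual must match a from-scratch refit by the oracle."""
        src = _cloud(rng, n=8)
        moved = src.coords.copy()
        moved[0] += [0.5, -0.3, 0.2]
        truth = RigidTransform.random(rng)
        dst = PointSet(truth.apply(moved), src.labels)
        res = fit_rigid(src, dst)
        oracle = brute_force_rigid(src.coords, dst.coords)
        oracle_res = np.linalg.norm(oracle.apply(src.coords) - dst.coords, axis=1)
        assert res.mean_error == pytest.approx(mean_error(oracle_res), abs=1e-6)

    def test_gate_flag_at_paper_threshold(self, rng):
        src = _cloud(rng, n=8)
        # displace one bead enough to push the RMS residual past 0.35 mm
        dst_coords = src.coords.copy()
        dst_coords[0] += [1.4, 0.0, 0.0]
        res = fit_rigid(src, PointSet(dst_coords, src.labels))
        assert res.mean_error > ME_THRESHOLD
        assert res.flags["me_ok"] is False
        assert res.flags["cn_ok"] is True


class TestConditionNumber:
    def test_cube_corners_are_perfectly_conditioned(self):
        corners = np.array(
            [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)], dtype=float
        )
        assert condition_number(corners) == pytest.approx(1.0, abs=1e-12)

    def test_collinear_markers_exceed_threshold(self):
        line = np.outer(np.arange(3.0), [1.0, 1.0, 0.0])
        assert condition_number(line) == CN_CAP
        assert condition_number(line) > CN_THRESHOLD

    def test_matches_direct_svd_oracle(self, rng):
        pts = rng.normal(scale=25.0, size=(10, 3))
        centred = pts - pts.mean(axis=0)
        # independent route: eigenvalues of the Gram matrix
        eig = np.sort(np.linalg.eigvalsh(centred.T @ centred))
        oracle = np.sqrt(eig[-1] / eig[0])
        assert condition_number(pts) == pytest.approx(oracle, rel=1e-9)

    def test_invariant_under_rigid_motion_and_scale(self, rng):
        pts = rng.normal(scale=25.0, size=(9, 3))
        cn = condition_number(pts)
        g = RigidTransform.random(rng)
        assert condition_number(g.apply(pts)) == pytest.approx(cn, rel=1e-9)
        assert condition_number(3.7 * pts) == pytest.approx(cn, rel=1e-9)


class TestFitModelPose:
    def test_exact_init_returns_pose_with_zero_residual(self, models, rng):
        model = models["stem"]
        truth = RigidTransform.random(rng)
        cloud = truth.apply_pointset(model.surface_points)
        res = fit_model_pose(model.surface_points, cloud, init=truth)
        assert res.converged
        assert res.transform.almost_equal(truth, tol=1e-9)
        assert res.mean_error < 1e-12

    @pytest.mark.parametrize("kind", ["stem", "cup"])
    def test_recovers_truth_from_perturbed_init(self, models, rng, kind):
        model = models[kind]
        truth = RigidTransform.random(rng)
        cloud = truth.apply_pointset(model.surface_points)
        wobble = RigidTransform(
            Rotation.from_rotvec(np.deg2rad(2.0) * np.array([1.0, -1.0, 0.5])).as_matrix(),
            np.array([0.8, -0.5, 0.3]),
        )
        res = fit_model_pose(model.surface_points, cloud, init=wobble.compose(truth))
        assert res.converged
        assert res.transform.almost_equal(truth, tol=1e-6)

    def test_noise_floor_and_consistency(self, models, rng):
        """With point noise SD sigma the RMS residual tracks sigma and
        the pose error stays well below it."""
        model = models["cup"]
        truth = RigidTransform.random(rng)
        sigma = 0.1
        errors, rms = [], []
        for _ in range(5):
            cloud = PointSet(
                truth.apply(model.surface_points.coords)
                + rng.normal(scale=sigma, size=model.surface_points.coords.shape)
            )
            res = fit_model_pose(model.surface_points, cloud, init=truth)
            rms.append(res.mean_error)
            errors.append(np.linalg.norm(res.transform.translation - truth.translation))
        assert np.mean(rms) == pytest.approx(sigma * np.sqrt(3), rel=0.35)
        assert np.mean(errors) < sigma

    def test_empty_cloud_raises(self, models):
        with pytest.raises(ValueError):
            fit_model_pose(
                models["cup"].surface_points,
                PointSet(np.empty((0, 3))),
                init=RigidTransform.identity(),
            )
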