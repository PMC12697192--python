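"""Anatomic frames, Cardan decomposition, mirroring, migration analysis."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from ctrsa import (
    RigidTransform,
    StudyConfig,
    TrueTrajectory,
    analyze_pair,
    apply_true_migration,
    build_stem_frame,
    build_table_frame,
    euclidean_total,
    make_baseline_examination,
    mirror_to_right,
)
from ctrsa.kinematics import (
    MigrationDOF,
    cardan_from_matrix,
    dof_to_frame_transform,
    frame_components,
    matrix_from_cardan,
    transform_in_frame,
)
from ctrsa.registration import DegenerateFitError

finite = st.floats(
    min_value=-1e3, max_value=1e3, allow_nan=False, allow_infinity=False
)


class TestEuclideanTotal:
    def test_pythagorean_triple(self):
        assert euclidean_total(1.0, 2.0, 2.0) == pytest.approx(3.0, abs=1e-12)

    def test_zero(self):
        assert euclidean_total(0.0, 0.0, 0.0) == 0.0

    @given(finite, finite, finite)
    def test_matches_sum_of_squares(self, x, y, z):
        assert euclidean_total(x, y, z) == pytest.approx(
            np.sqrt(x * x + y * y + z * z), rel=1e-12, abs=1e-12
        )

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            euclidean_total(np.inf, 0.0, 0.0)


class TestStemFrame:
    def test_canonical_landmarks_give_standard_basis(self):
        f = build_stem_frame((0, 0, 0), (0, 1, 0), (1, 1, 0))
        np.testing.assert_allclose(f.axes, np.eye(3), atol=1e-12)

    def test_right_handed_orthonormal_for_random_landmarks(self, rng):
        for _ in range(10):
            tip = rng.normal(scale=50, size=3)
            shoulder = tip + rng.normal(scale=50, size=3)
            neck = shoulder + rng.normal(scale=30, size=3)
            try:
                f = build_stem_frame(tip, shoulder, neck)
            except DegenerateFitError:
                continue
            np.testing.assert_allclose(f.axes.T @ f.axes, np.eye(3), atol=1e-9)
            np.testing.assert_allclose(np.cross(f.x, f.y), f.z, atol=1e-12)

    def test_equivariant_under_rotation(self, rng):
        tip, shoulder, neck = (0.0, 0, 0), (0, 100.0, 0), (30.0, 120, 0)
        base = build_stem_frame(tip, shoulder, neck)
        R = Rotation.random(random_state=7).as_matrix()
        rotated = build_stem_frame(R @ tip, R @ shoulder, R @ neck)
        np.testing.assert_allclose(rotated.axes, R @ base.axes, atol=1e-12)

    def test_parallel_neck_axis_raises(self):
        with pytest.raises(DegenerateFitError):
            build_stem_frame((0, 0, 0), (0, 1, 0), (0, 2, 0))

    def test_table_frame_is_identity_axes(self):
        f = build_table_frame()
        np.testing.assert_allclose(f.axes, np.eye(3), atol=0)
        f2 = build_table_frame(origin=(1.0, 2.0, 3.0))
        np.testing.assert_allclose(f2.axes, np.eye(3), atol=0)


class TestCardan:
    def test_roundtrip(self, rng):
        angles = rng.uniform(-30, 30, size=3)
        out = cardan_from_matrix(matrix_from_cardan(*angles))
        np.testing.assert_allclose(out, angles, atol=1e-10)

    def test_small_angle_skew_symmetric_consistency(self, rng):
        """At migration-scale angles the Cardan angles agree with
        first-order extraction from the skew-symmetric part; the error
        is the second-order commutator term (~|a x b|/2), below 0.01 deg
        for angles up to ~1 deg."""
        for _ in range(20):
            angles = rng.uniform(-1, 1, size=3)
            R = matrix_from_cardan(*angles)
            skew = 0.5 * (R - R.T)
            approx = np.rad2deg([skew[2, 1], skew[0, 2], skew[1, 0]])
            np.testing.assert_allclose(approx, angles, atol=0.01)

    def test_frame_transform_roundtrip(self, rng):
        from ctrsa.kinematics import AnatomicFrame

        A = Rotation.random(random_state=3).as_matrix()
        frame = AnatomicFrame(origin=rng.normal(size=3), axes=A)
        local = dof_to_frame_transform(0.5, -1.0, 0.2, 1.5, -0.7, 0.9)
        lab = transform_in_frame(frame, local)
        t, angles = frame_components(frame, lab)
        np.testing.assert_allclose(t, [0.5, -1.0, 0.2], atol=1e-10)
        np.testing.assert_allclose(angles, [1.5, -0.7, 0.9], atol=1e-10)


class TestMirrorToRight:
    def test_right_side_unchanged(self):
        d = MigrationDOF(1, 2, 3, 4, 5, 6, side="right")
        m = mirror_to_right(d)
        assert (m.Tx, m.Ty, m.Tz, m.Rx, m.Ry, m.Rz) == (1, 2, 3, 4, 5, 6)

    def test_left_side_negates_tx_ry_rz(self):
        d = MigrationDOF(1, 2, 3, 4, 5, 6, side="left")
        m = mirror_to_right(d)
        assert (m.Tx, m.Ty, m.Tz, m.Rx, m.Ry, m.Rz) == (-1, 2, 3, 4, -5, -6)
        assert m.Ttot == pytest.approx(d.Ttot, abs=1e-12)
        assert m.Rtot == pytest.approx(d.Rtot, abs=1e-12)

    @given(finite, finite, finite, finite, finite, finite)
    def test_totals_invariant(self, tx, ty, tz, rx, ry, rz):
        d = MigrationDOF(tx, ty, tz, rx, ry, rz, side="left")
        m = mirror_to_right(d)
        assert m.Ttot == pytest.approx(d.Ttot, rel=1e-12, abs=1e-12)
        assert m.Rtot == pytest.approx(d.Rtot, rel=1e-12, abs=1e-12)

    def test_involution_with_side_toggle(self):
        d = MigrationDOF(1, 2, 3, 4, 5, 6, side="left")
        once = mirror_to_right(d)
        from dataclasses import replace

        again = mirror_to_right(replace(once, side="left", mirrored=False))
        back = replace(again, side="left", mirrored=False)
        assert (back.Tx, back.Ry, back.Rz) == (d.Tx, d.Ry, d.Rz)

    def test_unknown_side_rejected(self):
        with pytest.raises(ValueError):
            mirror_to_right(MigrationDOF(0, 0, 0, 0, 0, 0, side="top"))


class TestAnalyzePair:
    @pytest.fixture()
    def scene(self, quiet_config, models, rng):
        base = make_baseline_examination("S001", "right", quiet_config, rng, models)
        return base

    def test_reposed_followup_measures_zero(self, scene, models, rng):
        zero = {
            seg: TrueTrajectory("S001", seg, {}, {}) for seg in ("stem", "cup")
        }
        pose = RigidTransform.random(rng)
        fu = apply_true_migration(scene, zero, 12.0, models, patient_pose=pose)
        for seg in ("stem", "cup"):
            res = analyze_pair(scene, fu, models[seg], segment=seg)
            assert abs(np.array(list(res.as_dict().values()))).max() < 1e-9

    def test_injected_subsidence_recovered_on_y_axis_only(self, scene, models):
        traj = TrueTrajectory("S001", "stem", {"Ty": -0.5 / 3.0}, {})
        fu = apply_true_migration(scene, traj, 3.0, models)
        res = analyze_pair(scene, fu, models["stem"], segment="stem")
        assert res.Ty == pytest.approx(-0.5, abs=1e-9)
        for k in ("Tx", "Tz", "Rx", "Ry", "Rz"):
            assert abs(getattr(res, k)) < 1e-9

    def test_collinear_reference_markers_raise(self, scene, models, rng):
        from dataclasses import replace

        from ctrsa import PointSet

        n = len(scene.femur_markers)
        line = PointSet(
            np.outer(np.linspace(0, 90, n), [0.1, 1.0, 0.0]) + [0, -150.0, 0],
            scene.femur_markers.labels,
        )
        bad_base = replace(scene, femur_markers=line)
        fu = apply_true_migration(
            bad_base, TrueTrajectory("S001", "stem", {}, {}), 3.0, models
        )
        with pytest.raises(DegenerateFitError):
            analyze_pair(bad_base, fu, models["stem"], segment="stem")

    def test_gate_flags_attached_not_dropped(self, scene, models, rng):
        """Near-collinear (but not singular) markers trip the CN gate;
        the record still carries values plus the flag."""
        from dataclasses import replace

        from ctrsa import PointSet

        n = len(scene.femur_markers)
        t = np.linspace(0, 90, n)
        nearly = np.outer(t, [0.0, 1.0, 0.0]) + rng.normal(scale=0.12, size=(n, 3))
        bad_base = replace(scene, femur_markers=PointSet(nearly, scene.femur_markers.labels))
        fu = apply_true_migration(
            bad_base, TrueTrajectory("S001", "stem", {}, {}), 3.0, models
        )
        res = analyze_pair(bad_base, fu, models["stem"], segment="stem")
        assert res.condition_number > 120
        assert "cn_ok" in res.flags

    def test_totals_consistent_with_components(self, scene, models):
        traj = TrueTrajectory(
            "S001", "cup", {"Tx": 0.1, "Ty": 0.2, "Rz": 0.3}, {}
        )
        fu = apply_true_migration(scene, traj, 3.0, models)
        res = analyze_pair(scene, fu, models["cup"], segment="cup")
        assert res.Ttot == pytest.approx(
            np.sqrt(res.Tx**2 + res.Ty**2 + res.Tz**2), abs=1e-12
        )
        assert res.Rtot == pytest.approx(
            np.sqrt(res.Rx**2 + res.Ry**2 + res.Rz**2), abs=1e-12
        )
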