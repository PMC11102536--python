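import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from rotometry import errors
from rotometry.mesh_core import TriangleMesh
from rotometry.registration import (
    RigidTransform,
    global_best_fit,
    kabsch,
    suspect_fit,
    three_point_align,
    tooth_best_fit,
    transfer_landmarks,
)
from rotometry.rotation_measure import RegistrationSettings, fit_case, measure_case


def rigid(deg, axis, t):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    R = Rotation.from_rotvec(axis * np.deg2rad(deg)).as_matrix()
    return RigidTransform(R, np.asarray(t, dtype=float))


TRIPLE = np.array([[0.0, 0.0, 0.0], [30.0, 2.0, 1.0], [12.0, 25.0, -3.0]])


class TestRigidTransform:
    def test_compose_inverse_identity(self):
        T = rigid(33.0, [1, 2, 3], [4, -5, 6])
        I = T.compose(T.inverse())
        np.testing.assert_allclose(I.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(I.translation, 0, atol=1e-9)

    def test_reflection_rejected(self):
        with pytest.raises(errors.InvalidInputError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestThreePointAlign:
    def test_identity(self):
        T = three_point_align(TRIPLE, TRIPLE)
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(T.translation, 0, atol=1e-9)

    def test_recovers_known_transform(self):
        Q = rigid(30.0, [0, 0, 1], [1, 2, 3])
        T = three_point_align(TRIPLE, Q.apply(TRIPLE))
        np.testing.assert_allclose(T.rotation, Q.rotation, atol=1e-9)
        np.testing.assert_allclose(T.translation, Q.translation, atol=1e-9)

    def test_inverse_property(self):
        tgt = rigid(25.0, [1, 1, 0], [0.5, -1, 2]).apply(TRIPLE)
        fwd = three_point_align(TRIPLE, tgt)
        bwd = three_point_align(tgt, TRIPLE)
        comp = fwd.compose(bwd)
        np.testing.assert_allclose(comp.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(comp.translation, 0, atol=1e-9)

    def test_collinear_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        with pytest.raises(errors.DegenerateConfigurationError):
            three_point_align(line, TRIPLE)

    def test_least_squares_optimum_vs_brute_force(self):
        """Perturbed (non-congruent) triples: residual must match an
        independent numerical search over rotations."""
        tgt = rigid(10.0, [0, 1, 1], [1, 0, 0]).apply(TRIPLE)
        tgt[1] += [0.5, 0.0, 0.0]
        T = three_point_align(TRIPLE, tgt)
        res_closed = np.sum((T.apply(TRIPLE) - tgt) ** 2)

        def objective(rv):
            R = Rotation.from_rotvec(rv).as_matrix()
            # Optimal translation for a given rotation is the centroid match.
            t = tgt.mean(axis=0) - R @ TRIPLE.mean(axis=0)
            return np.sum((TRIPLE @ R.T + t - tgt) ** 2)

        best = np.inf
        rng = np.random.default_rng(0)
        for _ in range(20):
            r = minimize(objective, rng.normal(scale=0.5, size=3), method="Nelder-Mead",
                         options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
            best = min(best, r.fun)
        assert res_closed == pytest.approx(best, abs=1e-8)
        assert res_closed <= best + 1e-10  # closed form is the optimum


class TestKabsch:
    def test_recovery_under_noise_free_map(self, rng):
        pts = rng.normal(size=(40, 3)) * 10
        Q = rigid(-70.0, [3, 1, 2], [9, 9, 9])
        T = kabsch(pts, Q.apply(pts))
        np.testing.assert_allclose(T.rotation, Q.rotation, atol=1e-9)


@pytest.fixture(scope="module")
def molar_mesh():
    from rotometry.synthetic_arch import make_tooth_template

    mesh, _ = make_tooth_template("first_molar")
    return mesh


class TestGlobalBestFit:
    def test_self_alignment(self, molar_mesh):
        res = global_best_fit(molar_mesh, molar_mesh)
        np.testing.assert_allclose(res.transform.rotation, np.eye(3), atol=1e-9)
        assert res.rms_mm < 1e-9

    def test_recover_known_transform(self, molar_mesh):
        Q = rigid(8.0, [0.2, 1, 0.1], [1.5, -2.0, 0.7])
        fixed = TriangleMesh(Q.apply(molar_mesh.vertices), molar_mesh.faces)
        tri_src = molar_mesh.vertices[:3] * 1.0
        init = three_point_align(tri_src, Q.apply(tri_src))
        res = global_best_fit(molar_mesh, fixed, init=init, max_iterations=200)
        dR = res.transform.rotation @ Q.rotation.T
        ang = np.degrees(np.linalg.norm(Rotation.from_matrix(dR).as_rotvec()))
        assert ang < 0.1
        np.testing.assert_allclose(res.transform.translation, Q.translation, atol=0.01)

    def test_rms_monotone_non_increasing(self, clean_case):
        case, _ = clean_case
        init = three_point_align(case.init_points("T1"), case.init_points("T0"))
        res = global_best_fit(case.meshes["T1"], case.meshes["T0"], init=init)
        hist = np.asarray(res.rms_history)
        assert np.all(np.diff(hist) <= 1e-12)
        assert res.iterations <= 50
        assert res.rms_mm <= hist[0]

    def test_noise_floor(self, rng, molar_mesh):
        sd = 0.05
        noisy = TriangleMesh(
            molar_mesh.vertices + rng.normal(0, sd, molar_mesh.vertices.shape),
            molar_mesh.faces,
        )
        res = global_best_fit(molar_mesh, noisy)
        assert res.rms_mm < 2 * sd

    def test_empty_and_nonfinite_rejected(self, molar_mesh):
        with pytest.raises(errors.InvalidInputError):
            global_best_fit(None, molar_mesh)
        bad = molar_mesh.copy()
        bad.vertices[0, 0] = np.inf
        with pytest.raises(errors.InvalidInputError):
            global_best_fit(bad, molar_mesh)


class TestToothBestFit:
    def test_null_motion_under_correct_segmentation(self, clean_case):
        """A tooth that did not move is recovered as (near) identity even
        though its neighbors rotated."""
        case, truth = clean_case
        # Fabricate a target where tooth A stays and the rest follows T1.
        fdi = case.labels.teeth[2]
        idx = case.labels.assignments[fdi]
        v0 = case.meshes["T0"].vertices
        v1 = truth.global_T1.inverse().apply(case.meshes["T1"].vertices)
        v1 = v1.copy()
        v1[idx] = v0[idx]
        target = TriangleMesh(v1, case.meshes["T0"].faces)
        res = tooth_best_fit(
            fdi, case.meshes["T0"], case.labels, target, RigidTransform.identity(),
            max_iterations=500, tol=1e-9,
        )
        ang = np.degrees(
            np.linalg.norm(Rotation.from_matrix(res.transform.rotation).as_rotvec())
        )
        assert ang < 0.1

    def test_angle_recovery_against_truth(self, measured_clean):
        from tests.conftest import signed_truth

        case, truth, measurements = measured_clean
        expect = signed_truth(truth)
        for m in measurements:
            assert m.prescribed == pytest.approx(expect[m.tooth][0], abs=0.1)

    def test_small_submesh_rejected(self, clean_case):
        case, _ = clean_case
        from rotometry.mesh_core import ToothLabelMap

        tiny = ToothLabelMap({31: np.arange(5)}, {31: "central_incisor"})
        with pytest.raises(errors.InvalidSegmentationError):
            tooth_best_fit(
                31, case.meshes["T0"], tiny, case.meshes["T0"], RigidTransform.identity()
            )

    def test_gross_init_flagged(self, jitter_case):
        """A wildly wrong init can land in a wrong basin; the RMS flag fires."""
        case, truth = jitter_case
        fdi = case.labels.teeth[0]
        bad_init = rigid(40.0, [0, 0, 1], [8.0, -6.0, 2.0])
        res = tooth_best_fit(
            fdi, case.meshes["T0"], case.labels, case.meshes["T2"], bad_init,
            max_iterations=30,
        )
        assert suspect_fit(res, truth.jitter_sd_mm)


class TestTransferLandmarks:
    def test_identity(self, clean_case):
        case, _ = clean_case
        fdi = case.labels.teeth[0]
        lms = [lm for lm in case.landmarks_T0 if lm.tooth == fdi]
        from rotometry.registration import AlignmentResult

        fit = AlignmentResult(RigidTransform.identity(), 1, 0.0, 10)
        moved = transfer_landmarks(lms, fit, "T1")
        for a, b in zip(lms, moved):
            np.testing.assert_allclose(a.position, b.position)
            assert b.frame == "T1"
            assert b.role == a.role

    def test_pure_translation(self, clean_case):
        case, _ = clean_case
        fdi = case.labels.teeth[0]
        lms = [lm for lm in case.landmarks_T0 if lm.tooth == fdi]
        from rotometry.registration import AlignmentResult

        t = np.array([1.0, -2.0, 3.0])
        fit = AlignmentResult(RigidTransform(np.eye(3), t), 1, 0.0, 10)
        moved = transfer_landmarks(lms, fit, "T1")
        for a, b in zip(lms, moved):
            np.testing.assert_allclose(b.position - a.position, t)

    def test_tooth_mismatch_rejected(self, clean_case):
        case, _ = clean_case
        from rotometry.registration import AlignmentResult

        fit = AlignmentResult(RigidTransform.identity(), 1, 0.0, 10)
        mixed = [lm for lm in case.landmarks_T0[:4]]
        assert len({lm.tooth for lm in mixed}) > 1
        with pytest.raises(errors.InvalidInputError):
            transfer_landmarks(mixed, fit, "T1")


class TestPipelineRigidInvariance:
    def test_common_rigid_motion_leaves_angles_unchanged(self, measured_clean):
        case, truth, measurements = measured_clean
        Q = rigid(17.0, [1, 0.3, 2], [5, 6, -7])
        import copy

        moved = copy.copy(case)
        moved.meshes = {
            f: TriangleMesh(Q.apply(m.vertices), m.faces)
            for f, m in case.meshes.items()
        }
        moved.landmarks_T0 = [
            type(lm)(lm.tooth, lm.role, Q.apply(lm.position[None])[0], lm.frame)
            for lm in case.landmarks_T0
        ]
        ms2, problems = (
            measure_case(moved, fit_case(moved, RegistrationSettings()))
        )
        assert not problems
        base = {m.tooth: (m.prescribed, m.achieved) for m in measurements}
        for m in ms2:
            assert m.prescribed == pytest.approx(base[m.tooth][0], abs=0.05)
            assert m.achieved == pytest.approx(base[m.tooth][1], abs=0.05)
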