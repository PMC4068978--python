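"""Registration primitives against independent oracles and exact identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

import casttrack as ct
from casttrack.registration import (
    ICPParams, RigidTransform, compose, icp, invert, kabsch,
    merge_views, nearest_neighbors,
)
from conftest import random_rigid


def euler_zyx(angles):
    a, b, g = angles
    ca, sa, cb, sb, cg, sg = np.cos(a), np.sin(a), np.cos(b), np.sin(b), np.cos(g), np.sin(g)
    Rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    Ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    Rz = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def brute_force_rigid_fit(P, Q):
    """Independent rigid-fit oracle: coarse Euler-angle grid + local refinement.

    For each candidate rotation the optimal translation is closed-form
    (centroid matching), so the search runs over the three Euler angles only.
    """
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def cost(angles):
        R = euler_zyx(angles)
        return np.mean(np.sum((Pc @ R.T - Qc) ** 2, axis=1))

    grid = np.radians(np.arange(-180, 180, 30.0))
    starts = sorted(
        ((cost((a, b, g)), (a, b, g)) for a in grid for b in grid[:6] for g in grid),
        key=lambda t: t[0],
    )[:5]
    best = None
    for _, x0 in starts:
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    R = euler_zyx(best.x)
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    return R, t, best.fun


class TestKabsch:
    def test_identity_on_equal_clouds(self, rng):
        P = rng.normal(size=(8, 3))
        T = kabsch(P, P)
        assert np.allclose(T.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(T.translation, 0, atol=1e-12)

    def test_pure_translation(self, rng):
        P = rng.normal(size=(5, 3))
        T = kabsch(P, P + [1.0, 0.0, 0.0])
        assert np.allclose(T.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(T.translation, [1, 0, 0], atol=1e-12)

    def test_rz90_matches_brute_force(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0.3, 0.2, 1.0]])
        Rz90 = euler_zyx((0, 0, np.pi / 2))
        Q = P @ Rz90.T
        T = kabsch(P, Q)
        assert np.abs(T.rotation - Rz90).max() < 1e-9
        R_bf, _, f_bf = brute_force_rigid_fit(P, Q)
        assert np.abs(T.rotation - R_bf).max() < 1e-5
        fit = np.mean(np.sum((T.apply(P) - Q) ** 2, axis=1))
        assert fit <= f_bf + 1e-6

    @pytest.mark.parametrize("n_points", [4, 7, 10])
    def test_equals_brute_force_minimizer_on_noisy_instances(self, n_points, rng):
        # noisy pairs: the optimum is strictly interior, oracle must agree
        P = rng.normal(size=(n_points, 3)) * 3
        true = random_rigid(rng, max_angle_deg=50)
        Q = true.apply(P) + rng.normal(scale=0.05, size=P.shape)
        T = kabsch(P, Q)
        fit = np.mean(np.sum((T.apply(P) - Q) ** 2, axis=1))
        _, _, f_bf = brute_force_rigid_fit(P, Q)
        assert fit <= f_bf + 1e-6

    def test_reflection_is_never_returned(self, rng):
        # mirrored target tempts the SVD solution into det = -1
        P = rng.normal(size=(6, 3))
        Q = P * [1, 1, -1]
        T = kabsch(P, Q)
        assert np.linalg.det(T.rotation) > 0.999999

    def test_collinear_points_raise(self):
        P = np.outer(np.arange(4.0), [1.0, 2.0, 0.5])
        with pytest.raises(ct.DegeneracyError):
            kabsch(P, P + 1.0)

    def test_too_few_points_raise(self):
        with pytest.raises(ct.DegeneracyError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_recovers_random_rigid_motion_exactly(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(12, 3)) * 5
        true = random_rigid(rng, max_angle_deg=179)
        T = kabsch(P, true.apply(P))
        assert np.abs(T.rotation - true.rotation).max() < 1e-9
        assert np.abs(T.translation - true.translation).max() < 1e-8


class TestNearestNeighbors:
    def test_query_at_reference_point(self, rng):
        ref = rng.normal(size=(20, 3))
        idx, dist = nearest_neighbors(ref, ref[[7]])
        assert idx[0] == 7 and dist[0] == 0.0

    def test_matches_exhaustive_scan(self, rng):
        ref = rng.normal(size=(200, 3))
        q = rng.normal(size=(200, 3))
        idx, dist = nearest_neighbors(ref, q)
        d2 = np.linalg.norm(q[:, None, :] - ref[None, :, :], axis=2)
        assert np.array_equal(idx, d2.argmin(axis=1))
        assert np.allclose(dist, d2.min(axis=1), atol=1e-12)

    def test_equidistant_tie_returns_lower_index(self):
        ref = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0]])
        idx, dist = nearest_neighbors(ref, np.array([[0.0, 0.0, 0.0]]))
        assert idx[0] == 0
        assert np.isclose(dist[0], 1.0)

    def test_empty_reference_raises(self):
        with pytest.raises((ct.DegeneracyError, ct.ConfigurationError)):
            nearest_neighbors(np.empty((0, 3)), np.zeros((1, 3)))


class TestICP:
    def test_identity_for_identical_clouds(self, rng):
        P = rng.normal(size=(100, 3))
        T, rms, n_iter = icp(P, P)
        assert rms < 1e-12
        assert n_iter <= 2
        assert np.allclose(T.rotation, np.eye(3), atol=1e-9)

    def test_recovers_known_transform_noiseless(self, small_arch):
        tooth = small_arch.tooth_points(14)
        true = ct.RigidTransform(euler_zyx((0, 0, np.radians(5.0))), [0.5, 0.0, 0.0])
        T, rms, _ = icp(tooth, true.apply(tooth))
        angle_err = np.degrees(np.arccos(np.clip(
            (np.trace(T.rotation.T @ true.rotation) - 1) / 2, -1, 1)))
        assert angle_err < 0.01
        assert np.abs(T.translation - true.translation).max() < 1e-3
        assert rms < 1e-6

    def test_robust_to_uniform_outliers(self, small_arch, rng):
        tooth = small_arch.tooth_points(14)
        true = ct.RigidTransform(euler_zyx((0, 0, np.radians(5.0))), [0.5, 0.0, 0.0])
        target = true.apply(tooth)
        src = tooth.copy()
        n_out = int(0.1 * len(src))
        src[:n_out] = rng.uniform(-30, 30, size=(n_out, 3))
        T, _, _ = icp(src, target, params=ICPParams(trim_fraction=0.15))
        angle_err = np.degrees(np.arccos(np.clip(
            (np.trace(T.rotation.T @ true.rotation) - 1) / 2, -1, 1)))
        assert angle_err < 0.1
        assert np.abs(T.translation - true.translation).max() < 0.01

    def test_trimmed_rms_is_monotone_nonincreasing(self, rng):
        for _ in range(20):
            P = rng.normal(size=(80, 3)) * 4
            Q = random_rigid(rng, max_angle_deg=20, max_shift=2).apply(P)
            Q += rng.normal(scale=0.05, size=Q.shape)
            hist = []
            icp(P, Q, rms_history=hist)
            diffs = np.diff(hist)
            assert (diffs <= 1e-12).all(), f"RMS increased: {hist}"

    def test_too_small_clouds_raise(self):
        with pytest.raises(ct.DegeneracyError):
            icp(np.zeros((4, 3)), np.zeros((4, 3)))


class TestMergeViews:
    def test_single_identity_view_unchanged(self, rng):
        P = rng.normal(size=(30, 3))
        out = merge_views([P], [RigidTransform.identity()])
        assert np.array_equal(out, P)

    def test_two_identity_copies_concatenate(self, rng):
        P = rng.normal(size=(30, 3))
        out = merge_views([P, P], [RigidTransform.identity()] * 2)
        assert out.shape == (60, 3)

    def test_mismatched_lengths_raise(self, rng):
        with pytest.raises(ct.ConfigurationError):
            merge_views([rng.normal(size=(5, 3))], [])

    def test_four_views_reassemble_the_arch(self, small_arch, rng):
        # four overlapping "scanner views" under known poses merge back
        cloud = small_arch.points
        views, transforms = [], []
        for k in range(4):
            pose = random_rigid(rng, max_angle_deg=30, max_shift=8)
            sel = slice(k * len(cloud) // 5, min(len(cloud), (k + 2) * len(cloud) // 5))
            views.append(invert(pose).apply(cloud[sel]))
            transforms.append(pose)
        merged = merge_views(views, transforms)
        _, dist = nearest_neighbors(cloud, merged)
        assert np.sqrt(np.mean(dist**2)) < 0.01

    def test_refine_corrects_small_pose_errors(self, small_arch, rng):
        # each view is the full cloud under a slightly mis-calibrated pose;
        # ICP refinement against the running merge recovers the alignment
        cloud = small_arch.points
        views, transforms = [cloud], [RigidTransform.identity()]
        for _ in range(3):
            pose = random_rigid(rng, max_angle_deg=20, max_shift=5)
            wobble = random_rigid(rng, max_angle_deg=0.5, max_shift=0.05)
            views.append(invert(compose(pose, wobble)).apply(cloud))
            transforms.append(pose)
        merged = merge_views(views, transforms, refine=True)
        _, dist = nearest_neighbors(cloud, merged)
        assert np.sqrt(np.mean(dist**2)) < 0.01


class TestComposeInvert:
    def test_invert_identity(self):
        T = invert(RigidTransform.identity())
        assert np.allclose(T.matrix, np.eye(4), atol=1e-15)

    def test_compose_with_inverse_is_identity(self, rng):
        a = random_rigid(rng)
        assert np.abs(compose(a, invert(a)).matrix - np.eye(4)).max() < 1e-12

    def test_compose_applies_b_then_a(self, rng):
        a, b = random_rigid(rng), random_rigid(rng)
        x = rng.normal(size=(7, 3))
        assert np.allclose(compose(a, b).apply(x), a.apply(b.apply(x)), atol=1e-10)

    def test_associativity(self, rng):
        a, b, c = (random_rigid(rng) for _ in range(3))
        lhs = compose(compose(a, b), c).matrix
        rhs = compose(a, compose(b, c)).matrix
        assert np.abs(lhs - rhs).max() < 1e-12


class TestRigidTransformValidation:
    def test_rejects_non_orthonormal(self):
        with pytest.raises(ct.ConfigurationError):
            RigidTransform(np.eye(3) * 1.001, np.zeros(3))

    def test_rejects_reflection(self):
        with pytest.raises(ct.ConfigurationError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_matrix_round_trip(self, rng):
        a = random_rigid(rng)
        b = RigidTransform.from_matrix(a.matrix)
        assert np.abs(a.matrix - b.matrix).max() < 1e-15
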