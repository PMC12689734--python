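"""Normalization, residuals, ICP and globally optimal coarse registration."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from vesselreg.features import FeatureCurve
from vesselreg.io_core import RigidTransform
from vesselreg.registration import (
    GoIcpParams,
    IcpParams,
    goicp_coarse,
    icp_fine,
    normalize_pair,
    register_features,
    trimmed_residual,
)

from conftest import random_rigid


def tree_feature_points(seed: int, n_branches: int = 4, spacing: float = 2.0) -> np.ndarray:
    """Centerline samples of a seeded synthetic tree, as a feature-like cloud.

    Sample positions are jittered: exactly uniform spacing would give the
    cloud a discrete translation symmetry along each curve.
    """
    from vesselreg.synthetic import VesselTreeSpec, generate_vessel_tree

    rng = np.random.default_rng(seed + 991)
    tree = generate_vessel_tree(VesselTreeSpec(n_branches=n_branches, seed=seed))
    pts = []
    for poly in tree.polylines:
        seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        steps = rng.uniform(0.5, 1.5, int(cum[-1] / spacing) + 2) * spacing
        t = np.cumsum(steps)
        t = t[t < cum[-1]]
        pts.append(np.column_stack([np.interp(t, cum, poly[:, k]) for k in range(3)]))
    return np.vstack(pts)


def as_curves(points_list):
    return [FeatureCurve(p) for p in points_list]


class TestNormalizePair:
    def test_identical_clouds_map_identically(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(50, 3)) * 30
        a, b, _ = normalize_pair(pts, pts)
        np.testing.assert_allclose(a, b, atol=1e-15)

    def test_denormalized_identity_is_identity(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(40, 3)) * 20
        _, _, norm = normalize_pair(pts, pts + 5.0)
        T = norm.denormalize_transform(RigidTransform.identity())
        np.testing.assert_allclose(T.as_matrix(), np.eye(4), atol=1e-12)

    def test_scale_matches_direct_extent(self):
        # a cloud spanning 200 mm maps into the unit-radius cube: scale 2/200
        pts = np.array([[0.0, 0, 0], [200.0, 0, 0], [100.0, 50, 0]])
        a, b, norm = normalize_pair(pts, pts)
        assert norm.scale == pytest.approx(2.0 / 200.0)
        joint = np.vstack([a, b])
        assert (joint.max(axis=0) - joint.min(axis=0)).max() == pytest.approx(2.0)

    def test_denormalization_round_trips_rigid_transform(self):
        rng = np.random.default_rng(2)
        src = rng.normal(size=(30, 3)) * 40
        T_mm = random_rigid(rng, 90, 30)
        tgt = T_mm.apply(src)
        s_n, t_n, norm = normalize_pair(src, tgt)
        # the transform mapping s_n onto t_n, denormalized, must equal T_mm
        R = T_mm.rotation
        t_norm = norm.forward(T_mm.apply(np.zeros((1, 3))))[0] - R @ norm.forward(np.zeros((1, 3)))[0]
        T_back = norm.denormalize_transform(RigidTransform(R, t_norm))
        np.testing.assert_allclose(T_back.apply(src), tgt, atol=1e-9)


class TestTrimmedResidual:
    def test_perfect_alignment_is_zero(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(25, 3)) * 10
        assert trimmed_residual(pts, pts, RigidTransform.identity(), 0.1) == 0.0

    def test_outlier_excluded_by_trimming(self):
        rng = np.random.default_rng(4)
        target = rng.normal(size=(30, 3)) * 10
        source = target[:10] + rng.normal(0, 0.1, (10, 3))
        source = np.vstack([source, [[1000.0, 0, 0]]])  # gross outlier, 1/11 of points
        mse = trimmed_residual(source, target, RigidTransform.identity(), 0.1)
        d, _ = cKDTree(target).query(source[:10])
        assert mse == pytest.approx((d**2).mean(), rel=1e-12)

    def test_zero_trim_matches_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        source = rng.uniform(0, 20, (40, 3))
        target = rng.uniform(0, 20, (35, 3))
        T = random_rigid(rng, 20, 5)
        mse = trimmed_residual(source, target, T, 0.0)
        moved = T.apply(source)
        d2 = ((moved[:, None, :] - target[None, :, :]) ** 2).sum(axis=2).min(axis=1)
        assert mse == pytest.approx(d2.mean(), rel=1e-12)


class TestIcpFine:
    def test_already_aligned_converges_immediately(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(50, 3)) * 15
        res = icp_fine(pts, pts, RigidTransform.identity())
        assert res.rmse == pytest.approx(0.0, abs=1e-12)
        assert res.iterations <= 1

    def test_pure_translation_recovered_exactly(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(60, 3)) * 15
        target = pts + np.array([2.0, 0.0, 0.0])
        res = icp_fine(pts, target, RigidTransform.identity())
        np.testing.assert_allclose(res.transform.translation, [2, 0, 0], atol=1e-6)
        assert res.rmse < 1e-6

    def test_iteration_cap_honored(self):
        # adversarial: two interleaved lattices keep ICP limping along
        rng = np.random.default_rng(8)
        a = rng.uniform(0, 50, (200, 3))
        b = rng.uniform(0, 50, (200, 3))
        res = icp_fine(a, b, RigidTransform.identity(), IcpParams())
        assert res.iterations <= 20

    def test_residual_trace_monotone_nonincreasing(self):
        rng = np.random.default_rng(9)
        src = rng.normal(size=(80, 3)) * 20
        tgt = random_rigid(rng, 10, 5).apply(src)
        res = icp_fine(src, tgt, RigidTransform.identity())
        trace = np.asarray(res.stage_trace)
        assert np.all(np.diff(trace) <= 1e-9)

    def test_returned_transform_is_rigid(self):
        rng = np.random.default_rng(10)
        src = rng.normal(size=(40, 3)) * 10
        tgt = random_rigid(rng, 30, 10).apply(src)
        res = icp_fine(src, tgt, RigidTransform.identity())
        R = res.transform.rotation
        np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)


class TestGoIcpCoarse:
    def test_large_misalignment_recovered(self):
        # the full branching set: a lone smooth trunk would be tangentially
        # ambiguous (it can slide along itself at zero residual)
        rng = np.random.default_rng(11)
        src = tree_feature_points(seed=11, spacing=4.0)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        T_true = RigidTransform(
            Rotation.from_rotvec(np.deg2rad(40) * axis).as_matrix(),
            np.array([12.0, -9.0, 8.0]),
        )
        tgt = T_true.apply(src)
        res = goicp_coarse(src, tgt, GoIcpParams())
        dR = res.transform.rotation.T @ T_true.rotation
        ang = np.rad2deg(np.linalg.norm(Rotation.from_matrix(dR).as_rotvec()))
        assert ang < 1.0
        assert np.linalg.norm(res.transform.translation - T_true.translation) < 0.5
        assert res.converged

    def test_identity_for_identical_clouds(self):
        src = tree_feature_points(seed=12)
        res = goicp_coarse(src, src, GoIcpParams())
        assert res.rmse < 1e-6
        np.testing.assert_allclose(res.transform.rotation, np.eye(3), atol=1e-6)

    def test_invariant_to_point_order(self):
        rng = np.random.default_rng(13)
        src = tree_feature_points(seed=13)[:80]
        tgt = random_rigid(rng, 45, 15).apply(src)
        res1 = goicp_coarse(src, tgt, GoIcpParams())
        perm = rng.permutation(len(src))
        res2 = goicp_coarse(src[perm], tgt, GoIcpParams())
        np.testing.assert_allclose(
            res1.transform.as_matrix(), res2.transform.as_matrix(), atol=1e-6
        )


class TestRegisterFeatures:
    def test_identical_curves_give_identity(self):
        pts = tree_feature_points(seed=14)
        curves = as_curves([pts[:40], pts[40:90]])
        res = register_features(curves, curves)
        assert res.rmse < 1e-6
        np.testing.assert_allclose(res.transform.as_matrix(), np.eye(4), atol=1e-5)

    @pytest.mark.parametrize("seed", range(6))
    def test_two_stage_never_worse_than_coarse(self, seed):
        rng = np.random.default_rng(seed)
        pts = tree_feature_points(seed=seed, n_branches=3 + seed % 4)
        T = random_rigid(rng, 40, 15)
        noisy = pts + rng.normal(0, 0.3, pts.shape)
        src_curves = as_curves([noisy[:50], noisy[50:100], noisy[100:150]])
        tgt_pts = T.apply(pts)
        tgt_curves = as_curves([tgt_pts[:60], tgt_pts[60:130], tgt_pts[130:]])
        from vesselreg.registration import flatten_curves, _densify_polylines, flatten_curves_list, goicp_coarse

        src = flatten_curves(src_curves, seed=seed)
        tgt = _densify_polylines(flatten_curves_list(tgt_curves), 0.5)
        coarse = goicp_coarse(src, tgt, GoIcpParams())
        res = register_features(src_curves, tgt_curves, seed=seed)
        assert res.rmse <= coarse.rmse + 1e-9

    def test_inverse_consistency_on_clean_pair(self):
        rng = np.random.default_rng(15)
        pts = tree_feature_points(seed=15)
        T = random_rigid(rng, 25, 10)
        a = as_curves([pts[:80], pts[80:160]])
        tb = T.apply(pts)
        b = as_curves([tb[:80], tb[80:160]])
        r_ab = register_features(a, b)
        r_ba = register_features(b, a)
        np.testing.assert_allclose(
            r_ab.transform.as_matrix(),
            r_ba.transform.inverse().as_matrix(),
            atol=1e-3,
        )

    def test_results_independent_of_worker_bound(self):
        pts = tree_feature_points(seed=16)
        rng = np.random.default_rng(16)
        T = random_rigid(rng, 30, 10)
        a = as_curves([pts[:70], pts[70:]])
        b = as_curves([T.apply(pts)[:70], T.apply(pts)[70:]])
        r1 = register_features(a, b, icp=IcpParams(max_workers=1))
        r7 = register_features(a, b, icp=IcpParams(max_workers=7))
        np.testing.assert_array_equal(r1.transform.as_matrix(), r7.transform.as_matrix())


class TestRegisterCase:
    def test_self_case_recovers_identity(self, synth_contraction_params):
        from vesselreg.config import Config
        from vesselreg.io_core import EvalCase
        from vesselreg.registration import register_case
        from vesselreg.synthetic import VesselTreeSpec, generate_vessel_tree, render_cloud, SourceProfile

        tree = generate_vessel_tree(VesselTreeSpec(n_branches=4, seed=17))
        pc = render_cloud(tree, SourceProfile(surface_density=0.5, noise_sigma=0.1), seed=17)
        case = EvalCase(fixed=pc, moving=pc, ground_truth=RigidTransform.identity())
        cfg = Config(contraction=synth_contraction_params)
        res, rep = register_case(case, cfg)
        from vesselreg.metrics import transform_error

        assert transform_error(res.transform, RigidTransform.identity(), pc.points) < 0.5

    def test_direction_flag_inverts_transform(self, synth_contraction_params):
        from vesselreg.config import Config
        from vesselreg.io_core import EvalCase
        from vesselreg.registration import register_case
        from vesselreg.synthetic import VesselTreeSpec, generate_vessel_tree, render_cloud, SourceProfile

        tree = generate_vessel_tree(VesselTreeSpec(n_branches=4, seed=18))
        pc = render_cloud(tree, SourceProfile(surface_density=0.5, noise_sigma=0.05), seed=18)
        rng = np.random.default_rng(18)
        T = random_rigid(rng, 20, 10)
        moving = pc.with_points(T.inverse().apply(pc.points))
        case = EvalCase(fixed=pc, moving=moving)
        r_fwd, _ = register_case(case, Config(contraction=synth_contraction_params))
        r_rev, _ = register_case(
            case, Config(contraction=synth_contraction_params, direction="us_to_ct")
        )
        np.testing.assert_allclose(
            r_fwd.transform.as_matrix(),
            r_rev.transform.inverse().as_matrix(),
            atol=0.5,
        )
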