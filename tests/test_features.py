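"""Segment ordering, point assignment, centre refinement and curve fitting."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from vesselreg.features import (
    SegmentationParams,
    assign_vessel_points,
    downsample_ends,
    extract_features,
    fit_feature_curve,
    order_segment,
    refine_center,
    FeatureCurve,
)
from vesselreg.io_core import PointCloud, RigidTransform

from conftest import SYNTH_CONTRACTION, cylinder_cloud


class TestOrderSegment:
    def test_sorted_input_preserved(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        out = order_segment(pts)
        np.testing.assert_array_equal(out, pts)

    def test_reversed_input_same_output(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([np.sort(rng.uniform(0, 30, 15)), np.zeros(15), np.zeros(15)])
        a = order_segment(pts)
        b = order_segment(pts[::-1])
        # same geometric sequence, possibly traversed from the other end
        assert np.allclose(a, b) or np.allclose(a, b[::-1])

    def test_helix_ordering_matches_arc_length(self):
        # pitch much larger than radius: principal axis is the helix axis
        t = np.sort(np.random.default_rng(1).uniform(0, 4 * np.pi, 60))
        pts = np.column_stack([np.cos(t), np.sin(t), 10.0 * t])
        out = order_segment(pts, k_pca=60)
        expected = pts[np.argsort(pts[:, 2])]
        assert np.allclose(out, expected) or np.allclose(out, expected[::-1])

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            order_segment(np.zeros((5, 3)))


class TestAssignVesselPoints:
    def test_radius_boundary_closed(self):
        skel = np.array([[0.0, 0, 0]])
        orig = np.array([[14.0, 0, 0], [16.0, 0, 0], [15.0, 0, 0]])
        sets = assign_vessel_points(orig, skel, assign_radius=15.0)
        assert sorted(sets[0]) == [0, 2]  # 15 mm is included, 16 mm is not

    def test_point_claimed_by_nearest_only(self):
        skel = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        orig = np.array([[0.6, 0, 0]])
        sets = assign_vessel_points(orig, skel, assign_radius=15.0)
        assert len(sets[0]) == 0
        assert list(sets[1]) == [0]

    def test_union_matches_exhaustive_scan(self):
        rng = np.random.default_rng(2)
        skel = np.column_stack([np.linspace(0, 80, 9), np.zeros(9), np.zeros(9)])
        orig = rng.uniform([-20, -20, -20], [100, 20, 20], (400, 3))
        sets = assign_vessel_points(orig, skel, assign_radius=15.0)
        claimed = np.sort(np.concatenate([s for s in sets if len(s)]))
        d = np.linalg.norm(orig[:, None, :] - skel[None, :, :], axis=2)
        expected = np.flatnonzero(d.min(axis=1) <= 15.0)
        np.testing.assert_array_equal(claimed, expected)
        # uniqueness: no index twice
        assert len(claimed) == len(set(claimed))


class TestRefineCenter:
    def test_elliptic_ring_wall_points_and_center_exact(self):
        # slightly elliptic rings break the in-plane PCA degeneracy so the
        # "vertical" direction is exactly +/-y; the wall points A and B are
        # then the antipodal +/-y extremes and d is the exact 10 mm diameter
        th = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        ring = lambda z: np.column_stack(
            [6.0 * np.cos(th), 5.0 * np.sin(th), np.full(60, z)]
        )
        P = np.vstack([ring(-1.0), ring(0.0), ring(1.0)])
        C = np.zeros(3)
        c_prime, diag = refine_center(P, C, np.array([1.0, 0, 0]))
        assert diag["d"] == pytest.approx(10.0, abs=1e-9)
        np.testing.assert_allclose(c_prime, [0, 0, 0], atol=1e-9)

    def test_symmetric_set_fixed_point(self):
        rng = np.random.default_rng(3)
        half = rng.normal(size=(40, 3))
        P = np.vstack([half, -half])  # exactly centro-symmetric about origin
        c_prime, _ = refine_center(P, np.zeros(3), np.array([0.0, 0, 1.0]))
        np.testing.assert_allclose(c_prime, 0.0, atol=1e-9)

    def test_excludes_neighbouring_vessel_from_neighbour_set(self):
        # a second vessel inside the 15 mm assignment ball contaminates the
        # raw centroid; the d/2 neighbour disc must exclude it, keeping the
        # refined centre within the main tube's own footprint
        for trial in range(50):
            rng = np.random.default_rng(2000 + trial)
            th = rng.uniform(0, 2 * np.pi, 60)
            z = rng.uniform(-1.5, 1.5, 60)
            main = np.column_stack([2.0 * np.cos(th), 2.0 * np.sin(th), z])
            th2 = rng.uniform(0, 2 * np.pi, 18)
            other = np.column_stack(
                [9.0 + 1.5 * np.cos(th2), 1.5 * np.sin(th2), rng.uniform(-1.5, 1.5, 18)]
            )
            P = np.vstack([main, other]) + rng.normal(0, 0.15, (78, 3))
            C = P.mean(axis=0)
            c_prime, diag = refine_center(P, C, np.array([0.0, 0, 1.0]))
            assert diag["n_neighbors"] <= 60  # contaminant cluster excluded
            assert np.linalg.norm(c_prime[:2]) <= 2.0 + 3 * 0.15

    def test_missing_far_wall_stays_bounded(self):
        # one-sided coverage must never fling the centre outside the data
        for trial in range(50):
            rng = np.random.default_rng(1000 + trial)
            th = rng.uniform(-np.pi / 2, np.pi / 2, 80)
            z = rng.uniform(-2, 2, 80)
            P = np.column_stack([5 * np.cos(th), 5 * np.sin(th), z])
            P += rng.normal(0, 0.3, P.shape)
            c_prime, _ = refine_center(P, P.mean(axis=0), np.array([0.0, 0, 1.0]))
            assert np.all(c_prime >= P.min(axis=0) - 1e-12)
            assert np.all(c_prime <= P.max(axis=0) + 1e-12)

    def test_never_leaves_bounding_box(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            P = rng.normal(size=(30, 3)) * rng.uniform(0.5, 5)
            c_prime, _ = refine_center(P, P.mean(axis=0), np.array([0.0, 0, 1.0]))
            assert np.all(c_prime >= P.min(axis=0) - 1e-12)
            assert np.all(c_prime <= P.max(axis=0) + 1e-12)


class TestFitFeatureCurve:
    def test_exact_quadratic_reproduced(self):
        # quadratic component centred on a symmetric parameter grid has zero
        # covariance with the linear term, so the principal axis is exactly
        # +/-x and the model reproduces its own family to machine precision
        t = np.linspace(0.0, 1.0, 21)
        centers = np.column_stack([t, 0.8 * (t - 0.5) ** 2, np.zeros_like(t)])
        curve = fit_feature_curve(centers, curve_samples=21)
        d, _ = cKDTree(centers).query(curve.samples)
        assert d.max() < 1e-9

    def test_collinear_centers_give_straight_line(self):
        t = np.linspace(0, 10, 15)
        centers = np.column_stack([t, 2 * t, -t])
        curve = fit_feature_curve(centers, curve_samples=15)
        chord = curve.samples[-1] - curve.samples[0]
        chord = chord / np.linalg.norm(chord)
        rel = curve.samples - curve.samples[0]
        off_axis = rel - np.outer(rel @ chord, chord)
        assert np.abs(off_axis).max() < 1e-9

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        t_true = np.sort(rng.uniform(0, 1, 20))
        centers = np.column_stack(
            [3 * t_true - 1, t_true**2 + 0.5 * t_true, 2 - t_true**2]
        )
        centers = centers + rng.normal(0, 0.2, centers.shape)
        curve = fit_feature_curve(centers, curve_samples=25)

        # independent oracle: explicit normal equations on the same parameter
        axis = np.linalg.svd(centers - centers.mean(axis=0))[2][0]
        t = centers @ axis
        t = (t - t.min()) / (t.max() - t.min())
        V = np.vander(t, 3, increasing=True)
        coeffs = np.linalg.solve(V.T @ V, V.T @ centers)
        ts = np.linspace(0, 1, 25)
        expected = np.vander(ts, 3, increasing=True) @ coeffs
        if not np.allclose(curve.samples[0], expected[0], atol=1e-6):
            expected = expected[::-1]  # axis sign is arbitrary
        np.testing.assert_allclose(curve.samples, expected, atol=1e-9)

    def test_two_centers_passthrough(self):
        centers = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        curve = fit_feature_curve(centers)
        np.testing.assert_array_equal(curve.samples, centers)


class TestDownsampleEnds:
    def _curve(self, n, kind):
        t = np.linspace(0, 1, n)
        return FeatureCurve(np.column_stack([t, t, t]), segment_kind=kind)

    def test_branch_kept_indices(self):
        out = downsample_ends([self._curve(20, "branch")], 5)
        expected = np.linspace(0, 1, 20)[[0, 5, 10, 15, 19]]
        np.testing.assert_allclose(out[0].samples[:, 0], expected)

    def test_k1_is_identity(self):
        c = self._curve(20, "branch")
        out = downsample_ends([c], 1)
        np.testing.assert_array_equal(out[0].samples, c.samples)

    def test_trunk_untouched(self):
        c = self._curve(20, "trunk")
        out = downsample_ends([c], 5)
        np.testing.assert_array_equal(out[0].samples, c.samples)


class TestExtractFeatures:
    def test_straight_tube_gives_one_straight_curve(self, synth_contraction_params):
        # surface density ~0.5 pts/mm^2, the regime the contraction
        # neighbourhood size is matched to
        pc = cylinder_cloud(n=630, radius=2.5, length=80.0, seed=6)
        curves = extract_features(pc, synth_contraction_params, SegmentationParams())
        assert len(curves) == 1
        s = curves[0].samples
        chord = s[-1] - s[0]
        chord /= np.linalg.norm(chord)
        rel = s - s[0]
        off = rel - np.outer(rel @ chord, chord)
        # the residual bow reflects cross-section sampling noise (~16 points
        # per section at this density gives ~0.5 mm centre noise); it stays
        # well under half the tube radius
        assert np.linalg.norm(off, axis=1).max() < 1.2

    def test_branching_tree_curves_near_true_centerline(self, synth_contraction_params):
        from vesselreg.synthetic import VesselTreeSpec, generate_vessel_tree, render_cloud, SourceProfile

        tree = generate_vessel_tree(VesselTreeSpec(n_branches=3, seed=7))
        pc = render_cloud(tree, SourceProfile(surface_density=0.5, noise_sigma=0.0), seed=7)
        curves = extract_features(pc, synth_contraction_params, SegmentationParams())
        assert len(curves) >= 3
        cl = cKDTree(tree.all_centerline_points())
        all_d = []
        for c in curves:
            d, _ = cl.query(c.samples)
            all_d.append(d)
            # worst samples sit near bifurcations, where a cross-section
            # holds two merging lumens; they stay close to one tube diameter
            assert d.max() < 3.0, f"curve strays {d.max():.2f} mm from the centerline"
        assert np.concatenate(all_d).mean() < 1.0

    def test_rigid_equivariance(self, synth_contraction_params):
        from vesselreg.synthetic import VesselTreeSpec, generate_vessel_tree, render_cloud, SourceProfile

        tree = generate_vessel_tree(VesselTreeSpec(n_branches=3, seed=8))
        pc = render_cloud(tree, SourceProfile(surface_density=0.5, noise_sigma=0.1), seed=8)
        rng = np.random.default_rng(9)
        T = RigidTransform(Rotation.random(rng=rng).as_matrix(), rng.normal(size=3) * 15)
        a = extract_features(PointCloud(T.apply(pc.points)), synth_contraction_params, SegmentationParams())
        b = extract_features(pc, synth_contraction_params, SegmentationParams())
        pa = np.vstack([c.samples for c in a])
        pb = T.apply(np.vstack([c.samples for c in b]))
        d1, _ = cKDTree(pb).query(pa)
        d2, _ = cKDTree(pa).query(pb)
        assert (d1.mean() + d2.mean()) / 2 < 0.5

    def test_output_much_smaller_than_input(self, synth_contraction_params):
        from vesselreg.synthetic import VesselTreeSpec, generate_vessel_tree, render_cloud, SourceProfile

        tree = generate_vessel_tree(VesselTreeSpec(n_branches=4, seed=10))
        pc = render_cloud(tree, SourceProfile(surface_density=1.5, noise_sigma=0.1), seed=10)
        curves = extract_features(pc, synth_contraction_params, SegmentationParams())
        n_samples = sum(len(c.samples) for c in curves)
        assert n_samples < len(pc) / 10

    def test_deterministic(self, synth_contraction_params):
        pc = cylinder_cloud(n=1500, radius=2.0, length=60.0, seed=11)
        a = extract_features(pc, synth_contraction_params, SegmentationParams())
        b = extract_features(pc, synth_contraction_params, SegmentationParams())
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.samples, cb.samples)

    def test_human_profile_weights_sum_to_one(self, synth_contraction_params):
        from vesselreg.synthetic import VesselTreeSpec, generate_vessel_tree, render_cloud, SourceProfile

        tree = generate_vessel_tree(VesselTreeSpec(n_branches=3, seed=12))
        pc = render_cloud(tree, SourceProfile(surface_density=0.6, noise_sigma=0.1), seed=12)
        curves = extract_features(pc, synth_contraction_params, SegmentationParams(), profile="human")
        assert sum(c.weight for c in curves) == pytest.approx(1.0)
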