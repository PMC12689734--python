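"""Feature-curve extraction from segmented vascular point clouds.

Each skeleton segment claims the original vascular points within 15 mm of
its skeleton points (a point claimed by several skeleton points goes to the
nearest one). Per skeleton point the claimed set P is reduced to a refined
cross-section centre C': the nearest wall points A and B on either side of
the initial centre C along the local "vertical" (second principal) direction
give a diameter estimate d = |A - B|; the centroid of the points within d/2
of C is C'. Recentring from the wall geometry rather than the raw centroid
is what makes the features robust to one-sided coverage gaps in the
ultrasound cloud. The ordered C' of a segment are then fitted per coordinate
by a quadratic polynomial in the normalized axis parameter, yielding a
smooth feature curve sampled at a fixed number of points. In human mode the
curve ends are additionally downsampled and curves carry relative weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .contraction import ContractionParams, contract_point_cloud
from .io_core import PointCloud, voxel_downsample
from .skeleton_graph import (
    NodeKind,
    SkeletonSegment,
    build_mst,
    default_merge_radius,
    simplify_junctions,
    split_segments,
)

__all__ = [
    "SegmentationParams",
    "FeatureCurve",
    "order_segment",
    "assign_vessel_points",
    "refine_center",
    "fit_feature_curve",
    "downsample_ends",
    "extract_features",
]

log = logging.getLogger(__name__)

_CONE_HALF_ANGLE = np.deg2rad(15.0)  # A/B wall search cone about +/- vertical


@dataclass
class SegmentationParams:
    """Parameters of segmentation and feature fitting.

    ``k_pca`` is the PCA neighbourhood for segment ordering (default 20),
    ``assign_radius`` the search radius around each skeleton point in mm
    (default 15), ``end_downsample_k`` the keep-every-k rate applied to
    terminal-branch curves in human mode (default 5), ``curve_samples`` the
    number of points sampled from each fitted quadratic. ``thin_edge`` (mm)
    spaces the contracted skeleton points before the spanning tree is built,
    which suppresses hair-like spurious branches; segments shorter than
    ``min_segment_length`` (mm) are treated as contraction debris and
    dropped. A quadratic is a local model: segments longer than
    ``max_fit_span`` (mm) are split into roughly equal spans and fitted
    piecewise.
    """

    k_pca: int = 20
    assign_radius: float = 15.0
    end_downsample_k: int = 5
    curve_samples: int = 25
    thin_edge: float = 2.0
    min_segment_length: float = 5.0
    max_fit_span: float = 40.0

    def __post_init__(self) -> None:
        if self.k_pca < 3:
            raise ValueError("k_pca must be >= 3")
        if self.assign_radius <= 0:
            raise ValueError("assign_radius must be > 0")
        if self.end_downsample_k < 1:
            raise ValueError("end_downsample_k must be >= 1")
        if self.curve_samples < 2:
            raise ValueError("curve_samples must be >= 2")
        if self.thin_edge < 0:
            raise ValueError("thin_edge must be >= 0")


@dataclass
class FeatureCurve:
    """An ordered polyline of fitted centre points with a registration weight."""

    samples: np.ndarray
    weight: float = 1.0
    segment_kind: str = "branch"  # branch | trunk

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3 or len(self.samples) < 2:
            raise ValueError("a feature curve needs >= 2 three-dimensional samples")
        if self.weight < 0:
            raise ValueError("curve weight must be non-negative")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.samples, axis=0), axis=1).sum())


def _longest_true_run(mask: np.ndarray) -> tuple[int, int] | None:
    """(start, stop) of the longest contiguous True run, or None if all False."""
    best, cur_start, best_span = None, None, 0
    for i, v in enumerate(list(mask) + [False]):
        if v and cur_start is None:
            cur_start = i
        elif not v and cur_start is not None:
            if i - cur_start > best_span:
                best, best_span = (cur_start, i), i - cur_start
            cur_start = None
    return best


def _principal_axes(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(first, second) principal components of a point set."""
    centered = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-12:
        raise ValueError("zero-variance point set has no principal direction")
    return vt[0], vt[1] if vt.shape[0] > 1 else np.zeros(3)


def order_segment(segment: SkeletonSegment | np.ndarray, k_pca: int = 20) -> np.ndarray:
    """Order a segment's skeleton points along their principal direction.

    The direction is the leading eigenvector of the covariance of (up to)
    ``k_pca`` segment points; its sign is chosen so the segment's first
    stored vertex projects lowest, which makes the ordering independent of
    the input permutation.
    """
    pts = segment.points if isinstance(segment, SkeletonSegment) else np.asarray(segment, float)
    if len(pts) < 2:
        raise ValueError("segment must contain at least 2 points")
    subset = pts[: min(k_pca, len(pts))]
    axis, _ = _principal_axes(subset if len(subset) >= 2 else pts)
    proj = pts @ axis
    if proj[0] > proj[-1]:
        axis = -axis
        proj = -proj
    order = np.lexsort((np.arange(len(pts)), proj))
    return pts[order]


def assign_vessel_points(
    original: PointCloud | np.ndarray,
    ordered_skeleton: np.ndarray,
    assign_radius: float = 15.0,
) -> list[np.ndarray]:
    """Claimed original-point index sets per skeleton point (closed radius).

    An original point within the radius of several skeleton points is
    assigned only to its nearest skeleton point.
    """
    orig = original.points if isinstance(original, PointCloud) else np.asarray(original, float)
    skel = np.asarray(ordered_skeleton, dtype=float)
    tree = cKDTree(skel)
    dist, nearest = tree.query(orig)
    sets: list[np.ndarray] = []
    for i in range(len(skel)):
        members = np.flatnonzero((nearest == i) & (dist <= assign_radius))
        if len(members) == 0:
            log.debug("skeleton point %d claims no original points", i)
        sets.append(members)
    return sets


def refine_center(
    segment_points: np.ndarray,
    C: np.ndarray,
    axis: np.ndarray,
    n_passes: int = 3,
) -> tuple[np.ndarray, dict]:
    """Recompute a cross-section centre from the local wall geometry.

    One pass finds the wall points A and B nearest to the current centre
    along the +/- vertical (second principal) direction, takes d = |A - B|
    as the local diameter estimate and recentres on the centroid of the
    neighbour set N (points within d/2 of the centre). The d/2 neighbourhood
    is what rejects points of other vessels pulled in by the wide assignment
    radius — the dominant error source near junctions — while keeping the
    estimate inside the local data. The pass is iterated ``n_passes`` times;
    it stops at a fixed point. Falls back to C' = C on degenerate input.
    Returns the refined centre C' and a diagnostics dict with A, B, d and
    the neighbour count of the final pass.
    """
    P = np.asarray(segment_points, dtype=float)
    C = np.asarray(C, dtype=float)
    diag: dict = {"A": None, "B": None, "d": 0.0, "n_neighbors": 0}
    if len(P) < 3:
        return C.copy(), diag
    centered = P - P.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if len(s) < 2 or s[1] < 1e-12:
        log.debug("degenerate cross-section (rank < 2); centre kept")
        return C.copy(), diag
    vertical = vt[1]
    cone = np.cos(_CONE_HALF_ANGLE)

    current = C.copy()
    for _ in range(max(1, n_passes)):
        rel = P - current
        dist = np.linalg.norm(rel, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = rel @ vertical / np.maximum(dist, 1e-300)

        def nearest_in(mask: np.ndarray) -> int | None:
            idx = np.flatnonzero(mask & (dist > 0))
            if len(idx) == 0:
                return None
            return int(idx[np.argmin(dist[idx])])

        ia = nearest_in(cosang >= cone)
        ib = nearest_in(cosang <= -cone)
        # a strict ray almost never hits a discrete point; fall back to the
        # nearest point in the half-space when the cone is empty
        if ia is None:
            ia = nearest_in(cosang > 0)
        if ib is None:
            ib = nearest_in(cosang < 0)
        if ia is None or ib is None:
            return current, diag
        A, B = P[ia], P[ib]
        d = float(np.linalg.norm(A - B))
        # A and B are rarely exactly antipodal, so |A-B| slightly
        # underestimates the diameter; a bare d/2 disc can then exclude the
        # whole wall ring and collapse the centroid onto one side
        members = np.flatnonzero(dist <= 1.25 * d / 2)
        diag.update({"A": A, "B": B, "d": d, "n_neighbors": int(len(members))})
        if len(members) < max(3, int(0.4 * len(P))):
            # a diameter estimate whose disc misses most of the section is a
            # failed wall search (empty cone, fallback hit a stray point);
            # recentring on that sliver would collapse onto one wall
            log.debug("neighbour disc covers too little of the section; centre kept")
            return current, diag
        new_center = P[members].mean(axis=0)
        if np.linalg.norm(new_center - current) < 1e-12:
            return new_center, diag
        current = new_center
    return current, diag


def fit_feature_curve(
    centers: np.ndarray,
    curve_samples: int = 25,
    segment_kind: str = "branch",
    weight: float = 1.0,
    outlier_residual: float | None = None,
) -> FeatureCurve:
    """Least-squares quadratic fit of ordered centre points.

    The parameter is the scalar projection of each centre onto the segment's
    principal axis, affinely mapped to [0, 1]; x, y, z are each fitted by a
    quadratic in that parameter and the curve is sampled uniformly. With
    ``outlier_residual`` set (mm), centres farther than that from the first
    fit are dropped and the curve refitted once — contraction debris and
    contaminated cross-sections otherwise bend the whole curve.
    """
    centers = np.asarray(centers, dtype=float)
    if len(centers) < 3:
        log.debug("fewer than 3 centres; passing polyline through unfitted")
        return FeatureCurve(samples=centers, weight=weight, segment_kind=segment_kind)
    axis, _ = _principal_axes(centers)
    t = centers @ axis
    t0, t1 = t.min(), t.max()
    if t1 - t0 < 1e-12:
        raise ValueError("degenerate segment: no extent along principal axis")
    t = (t - t0) / (t1 - t0)

    def _fit(tv: np.ndarray, cv: np.ndarray) -> np.ndarray:
        V = np.vander(tv, 3, increasing=True)  # [1, t, t^2]
        coeffs, *_ = np.linalg.lstsq(V, cv, rcond=None)
        return coeffs

    coeffs = _fit(t, centers)
    if outlier_residual is not None:
        resid = np.linalg.norm(
            np.vander(t, 3, increasing=True) @ coeffs - centers, axis=1
        )
        keep = resid <= outlier_residual
        if keep.sum() >= max(3, int(0.6 * len(t))) and not keep.all():
            coeffs = _fit(t[keep], centers[keep])
    ts = np.linspace(0.0, 1.0, curve_samples)
    samples = np.vander(ts, 3, increasing=True) @ coeffs
    return FeatureCurve(samples=samples, weight=weight, segment_kind=segment_kind)


def downsample_ends(curves: list[FeatureCurve], end_downsample_k: int) -> list[FeatureCurve]:
    """Keep every k-th sample of terminal-branch curves (first and last kept).

    Trunk curves pass through unchanged. This thins the end capillaries whose
    detail would otherwise dominate the correspondence search.
    """
    if end_downsample_k < 1:
        raise ValueError("end_downsample_k must be >= 1")
    if end_downsample_k == 1:
        return list(curves)
    out = []
    for c in curves:
        if c.segment_kind != "branch":
            out.append(c)
            continue
        n = len(c.samples)
        keep = list(range(0, n, end_downsample_k))
        if keep[-1] != n - 1:
            keep.append(n - 1)
        out.append(replace(c, samples=c.samples[keep]))
    return out


def extract_features(
    pc: PointCloud,
    contraction: ContractionParams | None = None,
    seg: SegmentationParams | None = None,
    profile: str = "phantom",
) -> list[FeatureCurve]:
    """Full feature pipeline: contract, build the tree, segment, refine, fit.

    ``profile`` selects the parameter profile: ``human`` additionally applies
    end downsampling and length-proportional curve weights (normalized to sum
    to one); ``phantom`` keeps uniform weights. Deterministic for fixed input.
    """
    if profile not in ("phantom", "human"):
        raise ValueError(f"unknown profile '{profile}'")
    if contraction is None:
        contraction = ContractionParams.for_profile(profile)
    if seg is None:
        seg = SegmentationParams()

    # work in the cloud's own principal frame: the voxel grids used for
    # downsampling and skeleton thinning then commute with rigid motions of
    # the input, making feature extraction equivariant
    center, R_canon = _canonical_frame(pc.points)
    pc = PointCloud((pc.points - center) @ R_canon.T, label=pc.label)

    skeleton = contract_point_cloud(pc, contraction)
    skel_pts = skeleton.points
    if seg.thin_edge > 0:
        skel_pts = voxel_downsample(PointCloud(skel_pts), seg.thin_edge).points
    graph = build_mst(skel_pts)
    graph = simplify_junctions(graph, default_merge_radius(graph))
    graph, segments = _prune_debris(graph, seg.min_segment_length)
    if not segments:
        raise ValueError("skeleton produced no segments; cloud too small or degenerate")

    # order every segment, then assign original points to skeleton points
    # globally: a point near a junction must not be claimed by two segments
    ordered_segments = []
    for segment in segments:
        if len(segment.points) < 2:
            continue
        ordered_segments.append((segment, order_segment(segment, seg.k_pca)))
    if not ordered_segments:
        raise ValueError("no usable segments after ordering")
    all_skel = np.vstack([o for _, o in ordered_segments])
    all_sets = assign_vessel_points(pc, all_skel, seg.assign_radius)
    cloud_tree = cKDTree(pc.points)
    junction_pts = graph.vertices[graph.junctions] if len(graph.junctions) else None

    curves: list[FeatureCurve] = []
    offset = 0
    for segment, ordered in ordered_segments:
        sets = all_sets[offset : offset + len(ordered)]
        offset += len(ordered)
        axis, _ = _principal_axes(ordered)
        centers, diams, support = [], [], []
        for members in sets:
            if len(members) < 3:
                continue
            P = pc.points[members]
            C = P.mean(axis=0)
            c_prime, diag = refine_center(P, C, axis)
            centers.append(c_prime)
            diams.append(diag["d"])
            support.append(diag["n_neighbors"])
        if len(centers) < 2:
            continue
        centers = np.asarray(centers)
        diams = np.asarray(diams)
        support = np.asarray(support)
        # gate on cross-section support: a reliable centre has several points
        # in its neighbour disc and a diameter consistent with the segment
        if len(centers) >= 4:
            d_med = float(np.median(diams[diams > 0])) if np.any(diams > 0) else 0.0
            ok = (support >= 5) & (diams <= max(3.0 * d_med, 1e-9))
            if junction_pts is not None and d_med > 0:
                # cross-sections at a bifurcation hold two merging lumens and
                # have no well-defined centre; skip the junction zone
                dj = np.min(
                    np.linalg.norm(centers[:, None, :] - junction_pts[None, :, :], axis=2),
                    axis=1,
                )
                ok = ok & (dj > d_med)
            if ok.sum() >= max(3, int(0.5 * len(centers))):
                centers = centers[ok]
        kind = "branch" if segment.is_branch else "trunk"
        # a quadratic is a local model: if one fit over the whole segment
        # underfits (long and high residual), fit piecewise instead
        whole = fit_feature_curve(centers, seg.curve_samples, kind, outlier_residual=2.0)
        # residuals against a densely sampled curve, so the sample spacing of
        # the stored curve does not masquerade as misfit
        dense = fit_feature_curve(centers, 8 * len(centers), kind, outlier_residual=2.0)
        resid, _ = cKDTree(dense.samples).query(centers)
        span = float(np.linalg.norm(np.diff(centers, axis=0), axis=1).sum())
        # robust misfit gauge: individual stray centres (sampling noise of
        # sparse sections) must not force a split — only structural misfit
        if span > seg.max_fit_span and np.median(resid) > 1.0:
            chunks = _split_by_span(centers, seg.max_fit_span)
        else:
            chunks = [centers]
        for chunk in chunks:
            curve = (
                whole
                if len(chunks) == 1
                else fit_feature_curve(chunk, seg.curve_samples, kind, outlier_residual=2.0)
            )
            curve = _clip_to_support(curve, cloud_tree, diams)
            if curve is not None:
                curves.append(curve)

    if not curves:
        raise ValueError("no feature curves could be extracted")

    if profile == "human":
        curves = downsample_ends(curves, seg.end_downsample_k)
        lengths = np.array([c.length for c in curves])
        total = lengths.sum()
        if total > 0:
            for c, ln in zip(curves, lengths):
                c.weight = float(ln / total)
    for c in curves:  # back to the input frame
        c.samples = c.samples @ R_canon + center
    return curves


def _canonical_frame(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and a deterministic principal-axes rotation for a cloud.

    Axis signs are fixed by making each eigenvector's largest-magnitude
    component positive; the third axis is the cross product so the frame is
    right-handed.
    """
    center = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - center, full_matrices=False)
    axes = []
    for i in range(2):
        v = vt[i]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        axes.append(v)
    axes.append(np.cross(axes[0], axes[1]))
    return center, np.asarray(axes)


def _prune_debris(graph, min_length: float, max_rounds: int = 10):
    """Iteratively remove hair branches shorter than ``min_length`` (mm).

    Deleting a debris branch lowers its junction's degree; if only two chains
    remain there the next split splices them into one segment, so artificial
    segment boundaries disappear along with the hairs.
    """
    from .skeleton_graph import SkeletonGraph

    segments = split_segments(graph)
    for _ in range(max_rounds):
        debris = [
            s for s in segments if s.is_branch and s.length < min_length
        ]
        if not debris or len(debris) == len(segments):
            break
        drop = set()
        for s in debris:
            for v in s.vertex_indices:
                drop.add(v)
            # keep the junction end so the remaining chains stay connected
            if s.end_kind == NodeKind.JUNCTION:
                drop.discard(s.vertex_indices[-1])
            if s.start_kind == NodeKind.JUNCTION:
                drop.discard(s.vertex_indices[0])
        keep = np.array([v for v in range(len(graph.vertices)) if v not in drop])
        if len(keep) < 2:
            break
        new_index = -np.ones(len(graph.vertices), dtype=int)
        new_index[keep] = np.arange(len(keep))
        edges = []
        for i, j, w in graph.edges:
            if new_index[i] >= 0 and new_index[j] >= 0:
                a, b = int(new_index[i]), int(new_index[j])
                edges.append((min(a, b), max(a, b), w))
        edges.sort()
        graph = SkeletonGraph(vertices=graph.vertices[keep], edges=edges)
        segments = split_segments(graph)
    return graph, segments


def _split_by_span(centers: np.ndarray, max_span: float) -> list[np.ndarray]:
    """Split ordered centres into contiguous chunks of arc length <= max_span.

    A quadratic is a local model; fitting one polynomial across an
    arbitrarily long (possibly compound) segment underfits its curvature.
    Chunks keep at least 3 centres; short remainders merge into the last
    chunk.
    """
    if len(centers) < 3 or max_span <= 0:
        return [centers]
    steps = np.linalg.norm(np.diff(centers, axis=0), axis=1)
    total = float(steps.sum())
    n_chunks = max(1, int(np.ceil(total / max_span)))
    if n_chunks == 1:
        return [centers]
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    bounds = np.linspace(0.0, total, n_chunks + 1)
    chunks = []
    start = 0
    for b in bounds[1:-1]:
        stop = int(np.searchsorted(cum, b))
        if stop - start >= 3:
            chunks.append(centers[start : stop + 1])  # share the boundary centre
            start = stop
    if len(centers) - start >= 3:
        chunks.append(centers[start:])
    elif chunks:
        chunks[-1] = np.vstack([chunks[-1], centers[start + 1 :]])
    else:
        chunks = [centers]
    return chunks


def _clip_to_support(
    curve: FeatureCurve, cloud_tree: cKDTree, diams: np.ndarray
) -> FeatureCurve | None:
    """Clip a fitted curve to imaged support; None when nothing remains.

    A genuine axis sample lies within about one tube radius of the wall
    points, while a curve bridging an unimaged region (coverage gap,
    contraction shortcut) floats in empty space and would bias the
    registration. The longest contiguous supported run is kept.
    """
    d_med = float(np.median(diams[diams > 0])) if np.any(diams > 0) else 0.0
    support_radius = 0.5 * d_med + 2.5
    dist_to_cloud, _ = cloud_tree.query(curve.samples)
    good = dist_to_cloud <= support_radius
    run = _longest_true_run(good)
    if run is None or run[1] - run[0] < 2:
        log.debug("segment curve unsupported by imaged points; dropped")
        return None
    if run[1] - run[0] < len(curve.samples):
        return replace(curve, samples=curve.samples[run[0] : run[1]])
    return curve
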