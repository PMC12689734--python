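"""Synthetic branching vascular phantoms rendered as cross-source cloud pairs.

A vessel tree is a quadratically bent trunk with branches sprouting at
seeded arc-length positions. Each tree is rendered twice as a tube-surface
point cloud under two source profiles: a dense, low-noise "CT-like" render
and a sparser, noisier "US-like" render with random dropout and an optional
coverage cone that truncates the field of view (mimicking the limited
scanning range of an ultrasound sweep). The moving CT-like cloud is placed
in its own frame by the inverse of a seeded ground-truth rigid transform,
so the generating centerlines and the transform serve as exact oracles for
every downstream accuracy property. Spherical tumor markers are recorded in
both frames and optionally voxelized on a 1 mm grid.

All randomness flows from explicit integer seeds; a case is reproducible
bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .io_core import EvalCase, PointCloud, RigidTransform, VoxelMask

__all__ = [
    "VesselTreeSpec",
    "SourceProfile",
    "VesselTree",
    "SyntheticCase",
    "generate_vessel_tree",
    "render_cloud",
    "make_case",
    "default_ct_profile",
    "default_us_profile",
]


@dataclass
class VesselTreeSpec:
    """Geometry of a liver-portal-vein-scale phantom tree (lengths in mm)."""

    n_branches: int = 5
    trunk_length: float = 150.0
    branch_length_range: tuple = (35.0, 60.0)
    branch_angle_range: tuple = (30.0, 70.0)
    radius_trunk: float = 2.5
    radius_branch: float = 1.5
    curvature: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trunk_length <= 0 or self.radius_trunk <= 0 or self.radius_branch <= 0:
            raise ValueError("lengths and radii must be > 0")
        if self.n_branches < 0:
            raise ValueError("n_branches must be >= 0")


@dataclass
class SourceProfile:
    """How one imaging source samples the vessel surface."""

    kind: str = "ct_like"  # ct_like | us_like
    surface_density: float = 0.5  # points per mm^2
    noise_sigma: float = 0.15  # mm, isotropic Gaussian
    dropout_fraction: float = 0.0
    coverage_cone: tuple | None = None  # (apex (3,), axis (3,), half_angle_deg)

    def __post_init__(self) -> None:
        if self.surface_density <= 0:
            raise ValueError("surface_density must be > 0")
        if not 0 <= self.dropout_fraction < 1:
            raise ValueError("dropout_fraction must lie in [0, 1)")


def default_ct_profile() -> SourceProfile:
    return SourceProfile(kind="ct_like", surface_density=0.5, noise_sigma=0.15)


def default_us_profile(tree_center: np.ndarray | None = None) -> SourceProfile:
    """Sparser, noisier render with 30% dropout; add a cone via make_case."""
    return SourceProfile(
        kind="us_like", surface_density=0.3, noise_sigma=0.4, dropout_fraction=0.3
    )


@dataclass
class VesselTree:
    """Centerline polylines plus per-polyline tube radii; polyline 0 is the trunk."""

    polylines: list
    radii: list
    spec: VesselTreeSpec

    def all_centerline_points(self) -> np.ndarray:
        return np.vstack(self.polylines)


@dataclass
class SyntheticCase:
    case: EvalCase
    tree: VesselTree
    centerlines_fixed: list = field(default_factory=list)


def _frame(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to the tangent (deterministic)."""
    t = tangent / np.linalg.norm(tangent)
    helper = np.array([1.0, 0.0, 0.0]) if abs(t[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    n1 = np.cross(t, helper)
    n1 /= np.linalg.norm(n1)
    n2 = np.cross(t, n1)
    return n1, n2


def _quadratic_polyline(
    start: np.ndarray,
    direction: np.ndarray,
    length: float,
    bend: np.ndarray,
    step: float = 1.0,
    bend3: np.ndarray | None = None,
) -> np.ndarray:
    """c(s) = start + s*direction + (s/L)^2 * bend [+ (s/L)^3 * bend3].

    The optional cubic term makes the curve non-planar; a purely quadratic
    space curve is a mirror-symmetric parabola, which no real vessel is and
    which would make the registration problem non-identifiable up to a flip.
    """
    n = max(int(np.ceil(length / step)) + 1, 3)
    s = np.linspace(0.0, length, n)
    u = (s / length) ** 2
    pts = start[None, :] + s[:, None] * direction[None, :] + u[:, None] * bend[None, :]
    if bend3 is not None:
        pts = pts + ((s / length) ** 3)[:, None] * bend3[None, :]
    return pts


def generate_vessel_tree(spec: VesselTreeSpec) -> VesselTree:
    """Deterministic (per seed) branching tree of quadratic space curves."""
    rng = np.random.default_rng(spec.seed)
    trunk_dir = np.array([0.0, 0.0, 1.0])
    bend_dir = np.array([1.0, 0.0, 0.0])
    out_of_plane = np.array([0.0, 1.0, 0.0])
    trunk = _quadratic_polyline(
        np.zeros(3),
        trunk_dir,
        spec.trunk_length,
        spec.curvature * bend_dir,
        bend3=0.6 * spec.curvature * out_of_plane,
    )
    polylines = [trunk]
    radii = [spec.radius_trunk]

    if spec.n_branches > 0:
        # sprout positions spread over the middle of the trunk, jittered
        fracs = np.linspace(0.25, 0.9, spec.n_branches)
        fracs = np.clip(fracs + rng.uniform(-0.04, 0.04, spec.n_branches), 0.05, 0.95)
        for f in fracs:
            i = int(f * (len(trunk) - 1))
            origin = trunk[i]
            tangent = trunk[min(i + 1, len(trunk) - 1)] - trunk[max(i - 1, 0)]
            tangent /= np.linalg.norm(tangent)
            n1, n2 = _frame(tangent)
            angle = np.deg2rad(rng.uniform(*spec.branch_angle_range))
            azimuth = rng.uniform(0, 2 * np.pi)
            direction = (
                np.cos(angle) * tangent
                + np.sin(angle) * (np.cos(azimuth) * n1 + np.sin(azimuth) * n2)
            )
            length = rng.uniform(*spec.branch_length_range)
            bend_mag = rng.uniform(0.0, 0.25) * length
            b1, b2 = _frame(direction)
            bend_az = rng.uniform(0, 2 * np.pi)
            bend = bend_mag * (np.cos(bend_az) * b1 + np.sin(bend_az) * b2)
            polylines.append(_quadratic_polyline(origin, direction, length, bend))
            radii.append(spec.radius_branch)
    return VesselTree(polylines=polylines, radii=radii, spec=spec)


def render_cloud(tree: VesselTree, profile: SourceProfile, seed: int) -> PointCloud:
    """Sample the tube surfaces of a tree under one source profile."""
    rng = np.random.default_rng(seed)
    chunks = []
    for poly, radius in zip(tree.polylines, tree.radii):
        seg_vec = np.diff(poly, axis=0)
        seg_len = np.linalg.norm(seg_vec, axis=1)
        areas = 2.0 * np.pi * radius * seg_len
        counts = rng.poisson(areas * profile.surface_density)
        for j, cnt in enumerate(counts):
            if cnt == 0:
                continue
            t = rng.uniform(0, 1, cnt)
            base = poly[j][None, :] + t[:, None] * seg_vec[j][None, :]
            n1, n2 = _frame(seg_vec[j])
            theta = rng.uniform(0, 2 * np.pi, cnt)
            pts = base + radius * (
                np.cos(theta)[:, None] * n1[None, :] + np.sin(theta)[:, None] * n2[None, :]
            )
            chunks.append(pts)
    if not chunks:
        raise ValueError("profile produced no surface samples; raise surface_density")
    pts = np.vstack(chunks)
    if profile.noise_sigma > 0:
        pts = pts + rng.normal(0.0, profile.noise_sigma, pts.shape)
    if profile.dropout_fraction > 0:
        keep = rng.uniform(0, 1, len(pts)) >= profile.dropout_fraction
        pts = pts[keep]
    if profile.coverage_cone is not None:
        apex, axis, half_angle_deg = profile.coverage_cone
        apex = np.asarray(apex, float)
        axis = np.asarray(axis, float)
        axis = axis / np.linalg.norm(axis)
        rel = pts - apex
        d = np.linalg.norm(rel, axis=1)
        cosang = rel @ axis / np.maximum(d, 1e-300)
        keep = cosang >= np.cos(np.deg2rad(half_angle_deg))
        pts = pts[keep]
        if len(pts) == 0:
            raise ValueError("coverage cone removed every point; widen the cone")
    label = "ct" if profile.kind == "ct_like" else "us"
    return PointCloud(points=pts, label=label)


def _sample_rigid(rng: np.random.Generator, max_rot_deg: float, max_trans_mm: float) -> RigidTransform:
    """Uniform random axis, uniform angle in [0, max], translation uniform in a ball."""
    if max_rot_deg <= 0 and max_trans_mm <= 0:
        return RigidTransform.identity()
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0, max(max_rot_deg, 0)))
    R = Rotation.from_rotvec(angle * axis).as_matrix()
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    t = v * max(max_trans_mm, 0) * rng.uniform(0, 1) ** (1.0 / 3.0)
    return RigidTransform(R, t)


def _voxelize_sphere(center: np.ndarray, radius: float, spacing: float = 1.0) -> VoxelMask:
    pad = radius + 2 * spacing
    origin = center - pad
    n = int(np.ceil(2 * pad / spacing)) + 1
    ax = origin[0] + spacing * np.arange(n)
    ay = origin[1] + spacing * np.arange(n)
    az = origin[2] + spacing * np.arange(n)
    X, Y, Z = np.meshgrid(ax, ay, az, indexing="ij")
    data = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2 <= radius**2
    return VoxelMask(data=data, origin=origin, spacing=spacing)


def make_case(
    spec: VesselTreeSpec | None = None,
    ct_profile: SourceProfile | None = None,
    us_profile: SourceProfile | None = None,
    transform_magnitude: tuple = (30.0, 20.0),
    n_tumors: int = 4,
    seed: int = 0,
    with_cone: bool = True,
    voxelize_tumors: bool = False,
    tumor_radius: float = 7.5,
) -> SyntheticCase:
    """Build a full cross-source evaluation case with known ground truth.

    The fixed US-like cloud lives in the canonical frame; the moving CT-like
    cloud is the same tree rendered with the CT profile and mapped by the
    inverse ground-truth transform, so T_gt(moving) aligns with fixed and
    recorded tumor centres satisfy center_fixed = T_gt(center_moving)
    exactly. Distinct sub-seeds drive the tree, each render, the transform
    and the tumor placement.
    """
    spec = spec or VesselTreeSpec(seed=seed)
    rng = np.random.default_rng(seed + 77_003)
    tree = generate_vessel_tree(spec)
    ct_profile = ct_profile or default_ct_profile()
    us_profile = us_profile or default_us_profile()

    if with_cone and us_profile.coverage_cone is None:
        # a fan-shaped field of view with its apex close to the anatomy, as an
        # abdominal sweep would have: truncates the far quarter of the tree
        cl = tree.all_centerline_points()
        center = cl.mean(axis=0)
        apex = center + np.array([0.0, -70.0, -35.0])
        axis = center - apex
        us_profile = SourceProfile(
            kind=us_profile.kind,
            surface_density=us_profile.surface_density,
            noise_sigma=us_profile.noise_sigma,
            dropout_fraction=us_profile.dropout_fraction,
            coverage_cone=(apex, axis, 35.0),
        )

    fixed = render_cloud(tree, us_profile, seed=seed + 1)
    ct_render = render_cloud(tree, ct_profile, seed=seed + 2)

    T_gt = _sample_rigid(rng, *transform_magnitude)
    T_inv = T_gt.inverse()
    moving = PointCloud(points=T_inv.apply(ct_render.points), label="ct")

    # tumors: spheres placed near, but clear of, the vessel tree
    cl = tree.all_centerline_points()
    lo, hi = cl.min(axis=0), cl.max(axis=0)
    centers_fixed = []
    tries = 0
    while len(centers_fixed) < n_tumors and tries < 200:
        tries += 1
        cand = rng.uniform(lo - 10, hi + 10)
        d = np.linalg.norm(cl - cand, axis=1).min()
        if tumor_radius + 2.0 < d < 40.0:
            centers_fixed.append(cand)
    centers_fixed = np.asarray(centers_fixed) if centers_fixed else None
    centers_moving = T_inv.apply(centers_fixed) if centers_fixed is not None else None

    masks = None
    if voxelize_tumors and centers_fixed is not None:
        masks = [_voxelize_sphere(c, tumor_radius) for c in centers_fixed]

    case = EvalCase(
        fixed=fixed,
        moving=moving,
        tumor_centers_fixed=centers_fixed,
        tumor_centers_moving=centers_moving,
        tumor_masks=masks,
        ground_truth=T_gt,
        meta={"seed": seed, "n_branches": spec.n_branches},
    )
    return SyntheticCase(case=case, tree=tree, centerlines_fixed=list(tree.polylines))
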