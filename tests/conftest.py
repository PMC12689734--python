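"""Shared fixtures: small geometric clouds and seeded tree cases."""

import numpy as np
import pytest

from vesselreg.contraction import ContractionParams
from vesselreg.features import SegmentationParams
from vesselreg.io_core import PointCloud


# contraction parameters matched to the locality of the desk-scale synthetic
# clouds (see docs/methods.md); used by every tree-level fixture and test
SYNTH_CONTRACTION = dict(k_neighbors=16)


@pytest.fixture
def synth_contraction_params() -> ContractionParams:
    return ContractionParams(**SYNTH_CONTRACTION)


@pytest.fixture
def seg_params() -> SegmentationParams:
    return SegmentationParams()


def cylinder_cloud(
    n: int = 2000,
    radius: float = 5.0,
    length: float = 100.0,
    seed: int = 0,
    noise: float = 0.0,
) -> PointCloud:
    """Points on the surface of a z-aligned cylinder starting at the origin."""
    rng = np.random.default_rng(seed)
    z = rng.uniform(0, length, n)
    theta = rng.uniform(0, 2 * np.pi, n)
    pts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), z])
    if noise > 0:
        pts = pts + rng.normal(0, noise, pts.shape)
    return PointCloud(pts)


@pytest.fixture
def cylinder() -> PointCloud:
    return cylinder_cloud()


def random_rigid(rng: np.random.Generator, max_deg: float = 180.0, max_mm: float = 50.0):
    from scipy.spatial.transform import Rotation

    from vesselreg.io_core import RigidTransform

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0, max_deg))
    R = Rotation.from_rotvec(angle * axis).as_matrix()
    t = rng.uniform(-max_mm, max_mm, 3)
    return RigidTransform(R, t)
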