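"""Evaluation metrics: skeleton RMSE, tumor TRE, Dice, VS, surface Dice.

Skeleton RMSE is the directed nearest-neighbour root-mean-square distance
from the transformed source features to the target features — the quantity
the fine ICP stage minimizes. TRE is the post-registration distance between
corresponding tumor mass centres. The volumetric scores compare voxel masks
on a common grid; surface Dice at tolerance tau counts the fraction of the
two surfaces lying within tau of each other (symmetric form).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .features import FeatureCurve
from .io_core import RigidTransform, VoxelMask

__all__ = [
    "EvaluationReport",
    "skeleton_rmse",
    "target_registration_error",
    "dice_and_vs",
    "surface_dice",
    "transform_error",
]


@dataclass
class EvaluationReport:
    """Scores of one registered case; absent metrics stay None, never 0."""

    rmse: float | None = None
    tre_per_tumor: list = field(default_factory=list)
    dice: float | None = None
    volume_similarity: float | None = None
    surface_dice_tau: float | None = None
    tau: float = 5.0

    def as_dict(self) -> dict:
        return {
            "rmse_mm": self.rmse,
            "tre_mm": list(self.tre_per_tumor),
            "dice": self.dice,
            "volume_similarity": self.volume_similarity,
            f"surface_dice_{self.tau:g}mm": self.surface_dice_tau,
        }


def _as_points(curves_or_points) -> np.ndarray:
    if isinstance(curves_or_points, np.ndarray):
        return curves_or_points
    if isinstance(curves_or_points, FeatureCurve):
        return curves_or_points.samples
    return np.vstack([c.samples if isinstance(c, FeatureCurve) else np.asarray(c) for c in curves_or_points])


def skeleton_rmse(a, b, T: RigidTransform | None = None) -> float:
    """Directed NN RMSE (mm) from transformed a-samples to b.

    When ``b`` is a list of feature curves the distance is taken to the
    curves themselves (their polylines densely resampled), so the stored
    sample spacing does not inflate the error; raw point arrays are compared
    point-to-point.
    """
    pa = _as_points(a)
    if isinstance(b, np.ndarray):
        pb = b
    else:
        from .registration import _densify_polylines, flatten_curves_list

        curves = [b] if isinstance(b, FeatureCurve) else list(b)
        if curves and isinstance(curves[0], FeatureCurve):
            pb = _densify_polylines(flatten_curves_list(curves), step=0.25)
        else:
            pb = _as_points(b)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("both feature sets must be nonempty")
    if T is not None:
        pa = T.apply(pa)
    d, _ = cKDTree(pb).query(pa)
    return float(np.sqrt(np.mean(d**2)))


def target_registration_error(
    center_moving: np.ndarray, center_fixed: np.ndarray, T: RigidTransform | None = None
) -> float:
    """Euclidean distance (mm) between the mapped moving centre and the fixed centre."""
    cm = np.asarray(center_moving, float).reshape(3)
    cf = np.asarray(center_fixed, float).reshape(3)
    if T is not None:
        cm = T.apply(cm[None, :])[0]
    return float(np.linalg.norm(cm - cf))


def transform_error(T_est: RigidTransform, T_true: RigidTransform, points: np.ndarray) -> float:
    """RMS discrepancy (mm) between two transforms over a reference point set."""
    pts = np.asarray(points, float)
    return float(np.sqrt(np.mean(np.sum((T_est.apply(pts) - T_true.apply(pts)) ** 2, axis=1))))


def dice_and_vs(mask_a: VoxelMask | np.ndarray, mask_b: VoxelMask | np.ndarray):
    """Dice overlap and volume similarity of two masks on the same grid.

    Returns (None, None) when both masks are empty (undefined, reported as
    absent rather than zero).
    """
    a = mask_a.data if isinstance(mask_a, VoxelMask) else np.asarray(mask_a, bool)
    b = mask_b.data if isinstance(mask_b, VoxelMask) else np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise ValueError(f"masks must share a voxel grid: {a.shape} vs {b.shape}")
    va, vb = int(a.sum()), int(b.sum())
    if va + vb == 0:
        return None, None
    inter = int((a & b).sum())
    dice = 2.0 * inter / (va + vb)
    vs = 1.0 - abs(va - vb) / (va + vb)
    return dice, vs


def surface_dice(surface_a: np.ndarray, surface_b: np.ndarray, tau: float = 5.0) -> float:
    """Symmetric surface Dice at tolerance tau (mm) between two surface samplings."""
    a = np.asarray(surface_a, float)
    b = np.asarray(surface_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both surfaces must be nonempty")
    if tau <= 0:
        raise ValueError("tau must be > 0")
    da, _ = cKDTree(b).query(a)
    db, _ = cKDTree(a).query(b)
    return float(((da <= tau).sum() + (db <= tau).sum()) / (len(a) + len(b)))
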