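"""Coarse curve-skeleton extraction by Laplacian point-cloud contraction.

The cloud is first voxel-downsampled, then iteratively shrunk by solving the
stacked least-squares system

    [ W_L L ]        [   0     ]
    [  W_H  ] X'  =  [ W_H X   ]

where L is an umbrella Laplacian over the symmetrized k-nearest-neighbour
graph with inverse-distance weights, W_L a global contraction weight grown
each iteration, and W_H per-point attraction weights that increase as a
point's neighbourhood collapses. The loop stops at ``max_iter`` or when the
total local extent changes by less than ``termination_ratio`` between
iterations. The result is a coarse skeleton: one contracted position per
downsampled input point, meant only as an intermediate structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .io_core import PointCloud, voxel_downsample

__all__ = [
    "ContractionParams",
    "CoarseSkeleton",
    "build_neighborhoods",
    "build_laplacian",
    "contract_point_cloud",
]

log = logging.getLogger(__name__)

_EPS_DIST = 1e-6  # mm floor for inverse-distance weights on coincident points


@dataclass
class ContractionParams:
    """Knobs of the contraction stage.

    Defaults follow the phantom profile: 0.8 mm voxel downsampling, k = 100
    neighbours, initial contraction weight 0.5, initial attraction weight 4
    (10 for the human profile), at most 10 iterations, termination ratio
    0.003. The growth factor and contraction-weight cap control the standard
    doubling schedule.
    """

    voxel_edge: float = 0.8
    k_neighbors: int = 100
    w_contract0: float = 0.5
    w_attract0: float = 4.0
    max_iter: int = 10
    termination_ratio: float = 0.003
    contract_growth: float = 2.0
    w_contract_max: float = 2048.0

    def __post_init__(self) -> None:
        if self.k_neighbors < 4:
            raise ValueError("k_neighbors must be >= 4")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0 < self.termination_ratio < 1:
            raise ValueError("termination_ratio must lie in (0, 1)")
        if self.contract_growth <= 1:
            raise ValueError("contract_growth must be > 1")

    @classmethod
    def for_profile(cls, profile: str, **overrides) -> "ContractionParams":
        base = {"phantom": 4.0, "human": 10.0}
        if profile not in base:
            raise ValueError(f"unknown profile '{profile}' (expected phantom|human)")
        kwargs = {"w_attract0": base[profile]}
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class CoarseSkeleton:
    points: np.ndarray
    source_index: np.ndarray
    iterations_run: int
    shrink_trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.source_index = np.asarray(self.source_index, dtype=int)
        if len(self.points) != len(self.source_index):
            raise ValueError("one source index per contracted point required")


def build_neighborhoods(points: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest Euclidean neighbours of each point (self excluded).

    Distance ties are broken toward the lower index so the table is unique.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n <= k:
        raise ValueError(f"need more than k={k} points (got {n}); lower k_neighbors")
    tree = cKDTree(points)
    dist, idx = tree.query(points, k=k + 1)
    # cKDTree already orders by distance; enforce lower-index-first on exact ties
    order = np.lexsort((idx, dist), axis=1)
    idx = np.take_along_axis(idx, order, axis=1)
    out = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        row = idx[i]
        row = row[row != i][:k]
        if len(row) < k:  # self missing from its own list (exact duplicates)
            row = np.concatenate([row, idx[i][-(k - len(row)):]])
        out[i] = row
    return out


def build_laplacian(points: np.ndarray, neighborhoods: np.ndarray) -> sp.csr_matrix:
    """Umbrella Laplacian on the symmetrized kNN graph.

    Off-diagonal entries are inverse-distance weights 1/max(d_ij, eps); the
    diagonal is minus the row sum, so rows sum to zero exactly.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    k = neighborhoods.shape[1]
    rows = np.repeat(np.arange(n), k)
    cols = neighborhoods.ravel()
    adj = sp.csr_matrix((np.ones(n * k), (rows, cols)), shape=(n, n))
    adj = adj.maximum(adj.T)  # symmetrize
    adj = sp.coo_matrix(adj)
    d = np.linalg.norm(points[adj.row] - points[adj.col], axis=1)
    if np.any(d < _EPS_DIST):
        log.warning("coincident points in neighbourhood graph; weights epsilon-floored")
    w = 1.0 / np.maximum(d, _EPS_DIST)
    W = sp.csr_matrix((w, (adj.row, adj.col)), shape=(n, n))
    deg = np.asarray(W.sum(axis=1)).ravel()
    return (W - sp.diags(deg)).tocsr()


def _local_extent(points: np.ndarray, neighborhoods: np.ndarray) -> np.ndarray:
    """Mean distance of each point to its (original) k nearest neighbours."""
    diffs = points[neighborhoods] - points[:, None, :]
    return np.linalg.norm(diffs, axis=2).mean(axis=1)


def contract_point_cloud(pc: PointCloud, params: ContractionParams) -> CoarseSkeleton:
    """Contract a vascular cloud toward its curve skeleton.

    The neighbourhood graph is built once on the downsampled cloud and kept
    fixed across iterations, which makes the contraction equivariant under
    rigid motions of the input.
    """
    down = voxel_downsample(pc, params.voxel_edge)
    pts0 = down.points
    n = len(pts0)
    if n <= params.k_neighbors:
        raise ValueError(
            f"downsampled cloud has {n} points but k_neighbors={params.k_neighbors}; "
            "lower k_neighbors or the voxel edge"
        )
    # provenance: nearest original point to each voxel centroid
    src_tree = cKDTree(pc.points)
    _, source_index = src_tree.query(pts0)

    nbrs = build_neighborhoods(pts0, params.k_neighbors)
    L = build_laplacian(pts0, nbrs)

    extent0 = _local_extent(pts0, nbrs)
    total0 = float(extent0.sum())
    w_l = params.w_contract0
    w_h = np.full(n, params.w_attract0)

    X = pts0.copy()
    trace: list[float] = []
    prev_total = total0
    iterations = 0
    for _ in range(params.max_iter):
        A_top = L.multiply(w_l).tocsr()
        M = (A_top.T @ A_top + sp.diags(w_h**2)).tocsc()
        rhs = (w_h**2)[:, None] * X
        try:
            solve = spla.factorized(M)
            X_new = np.column_stack([solve(rhs[:, c]) for c in range(3)])
        except RuntimeError:  # singular factorization: fall back to lsqr
            X_new = np.column_stack(
                [spla.lsqr(M, rhs[:, c], atol=1e-12, btol=1e-12)[0] for c in range(3)]
            )
        if not np.all(np.isfinite(X_new)):
            raise FloatingPointError(
                "contraction diverged (non-finite positions); "
                f"params: w_contract0={params.w_contract0}, w_attract0={params.w_attract0}"
            )
        X = X_new
        iterations += 1

        extent = _local_extent(X, nbrs)
        total = float(extent.sum())
        trace.append(total / total0)
        rel_change = abs(prev_total - total) / max(prev_total, 1e-300)
        prev_total = total

        w_l = min(w_l * params.contract_growth, params.w_contract_max)
        w_h = params.w_attract0 * extent0 / np.maximum(extent, _EPS_DIST)

        if rel_change < params.termination_ratio:
            break

    return CoarseSkeleton(
        points=X, source_index=source_index, iterations_run=iterations, shrink_trace=trace
    )
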