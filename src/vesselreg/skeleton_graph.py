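"""Graph structure on the coarse skeleton: MST, node classification, segments.

The contracted skeleton points are joined by the minimum spanning tree of
their complete Euclidean graph. Vertex degree then classifies skeleton
points: degree 1 = vessel endpoint, degree >= 3 = bifurcation/junction,
degree 2 = ordinary chain point. Nearby junctions are merged (contraction
tends to produce small junction clusters), and the tree is finally split
into segments running between nodes: each branch is the shortest path from
an endpoint to its geodesically nearest junction, and junction-junction
trunks are extracted from the remainder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import minimum_spanning_tree as _csgraph_mst

from .contraction import CoarseSkeleton

__all__ = [
    "SkeletonGraph",
    "SkeletonSegment",
    "NodeKind",
    "build_mst",
    "simplify_junctions",
    "split_segments",
]

log = logging.getLogger(__name__)


class NodeKind(str, Enum):
    ENDPOINT = "endpoint"
    JUNCTION = "junction"


@dataclass
class SkeletonGraph:
    """An undirected Euclidean tree over skeleton points."""

    vertices: np.ndarray
    edges: list  # (i, j, length) with i < j

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)

    @property
    def degree(self) -> np.ndarray:
        deg = np.zeros(len(self.vertices), dtype=int)
        for i, j, _ in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    @property
    def endpoints(self) -> np.ndarray:
        return np.flatnonzero(self.degree == 1)

    @property
    def junctions(self) -> np.ndarray:
        return np.flatnonzero(self.degree >= 3)

    def adjacency(self) -> list[list[tuple[int, float]]]:
        adj: list[list[tuple[int, float]]] = [[] for _ in range(len(self.vertices))]
        for i, j, w in self.edges:
            adj[i].append((j, w))
            adj[j].append((i, w))
        return adj


@dataclass
class SkeletonSegment:
    """An ordered run of skeleton vertices between two nodes."""

    vertex_indices: list
    points: np.ndarray
    start_kind: NodeKind
    end_kind: NodeKind

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def is_branch(self) -> bool:
        """Terminal segments (at least one endpoint end) are branches; the rest trunks."""
        return NodeKind.ENDPOINT in (self.start_kind, self.end_kind)


def _dedupe(points: np.ndarray, tol: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """Merge exactly coincident points (within tol); returns (unique, keep-index)."""
    keys = np.round(points / tol).astype(np.int64)
    _, keep = np.unique(keys, axis=0, return_index=True)
    keep.sort()
    return points[keep], keep


def build_mst(skeleton: CoarseSkeleton | np.ndarray) -> SkeletonGraph:
    """Minimum spanning tree of the complete Euclidean graph on skeleton points.

    Equal-weight ties are broken by the lexicographically smallest vertex-index
    pair, so the tree is unique and deterministic. For large skeletons the
    pairwise distance matrix is assembled blockwise; the result is identical
    to the naive dense construction.
    """
    raw = skeleton.points if isinstance(skeleton, CoarseSkeleton) else np.asarray(skeleton, float)
    pts, keep = _dedupe(raw)
    if len(keep) < len(raw):
        log.info("merged %d coincident skeleton points", len(raw) - len(keep))
    n = len(pts)
    if n == 1:
        return SkeletonGraph(vertices=pts, edges=[])
    if n < 2:
        raise ValueError("need at least 2 distinct points to build an MST")

    block = 2048 if n > 6000 else n
    dist = np.empty((n, n), dtype=np.float64)
    for s in range(0, n, block):
        e = min(s + block, n)
        dist[s:e] = np.linalg.norm(pts[s:e, None, :] - pts[None, :, :], axis=2)
    # strictly monotone tie-break: add an index-pair epsilon far below distance
    # resolution, so csgraph's MST picks the lexicographically smallest pair
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    tiny = 1e-12 * (np.minimum(ii, jj) * n + np.maximum(ii, jj)) / (n * n)
    tree = _csgraph_mst(np.triu(dist + tiny, k=1)).tocoo()
    edges = []
    for i, j in zip(tree.row, tree.col):
        a, b = (int(i), int(j)) if i < j else (int(j), int(i))
        edges.append((a, b, float(dist[a, b])))
    edges.sort()
    return SkeletonGraph(vertices=pts, edges=edges)


def _geodesic_distances(graph: SkeletonGraph, sources: np.ndarray) -> np.ndarray:
    n = len(graph.vertices)
    if not graph.edges:
        return np.zeros((len(sources), n))
    rows = [e[0] for e in graph.edges]
    cols = [e[1] for e in graph.edges]
    w = [e[2] for e in graph.edges]
    A = sp.csr_matrix((w, (rows, cols)), shape=(n, n))
    A = A + A.T
    from scipy.sparse.csgraph import dijkstra

    return dijkstra(A, directed=False, indices=sources)


def simplify_junctions(graph: SkeletonGraph, merge_radius: float) -> SkeletonGraph:
    """Collapse clusters of junctions closer than ``merge_radius`` along the tree.

    Junction vertices whose pairwise geodesic distance is below the radius are
    replaced by one vertex at their centroid; incident edges reconnect there.
    The output is again a tree.
    """
    junctions = graph.junctions
    if merge_radius <= 0 or len(junctions) < 2:
        return graph
    gd = _geodesic_distances(graph, junctions)[:, junctions]
    # connected components of the "closer than radius" relation among junctions
    close = sp.csr_matrix(gd < merge_radius)
    from scipy.sparse.csgraph import connected_components

    n_comp, labels = connected_components(close, directed=False)
    if n_comp == len(junctions):
        return graph

    n = len(graph.vertices)
    remap = np.arange(n)
    new_points = graph.vertices.copy()
    drop = np.zeros(n, dtype=bool)
    adj = graph.adjacency()
    for c in range(n_comp):
        members = junctions[labels == c]
        if len(members) < 2:
            continue
        rep = int(members.min())
        new_points[rep] = graph.vertices[members].mean(axis=0)
        # contract the connected subtree spanning the cluster (all vertices on
        # pairwise tree paths); contracting a connected subgraph keeps a tree
        cluster = {rep}
        for m in members:
            path = _tree_path(adj, rep, int(m))
            cluster.update(path)
        for m in cluster:
            remap[m] = rep
            if m != rep:
                drop[m] = True

    # rebuild edges under the merge; parallel edges/self-loops vanish
    merged_edges = set()
    for i, j, _ in graph.edges:
        a, b = remap[i], remap[j]
        if a == b:
            continue
        merged_edges.add((min(a, b), max(a, b)))
    keep = np.flatnonzero(~drop)
    if len(keep) < 2:
        raise ValueError(f"merge_radius={merge_radius} collapsed the whole skeleton")
    new_index = -np.ones(n, dtype=int)
    new_index[keep] = np.arange(len(keep))
    verts = new_points[keep]
    edges = []
    for a, b in merged_edges:
        i, j = int(new_index[a]), int(new_index[b])
        a2, b2 = (i, j) if i < j else (j, i)
        edges.append((a2, b2, float(np.linalg.norm(verts[a2] - verts[b2]))))
    edges.sort()
    out = SkeletonGraph(vertices=verts, edges=edges)
    if len(out.edges) != len(out.vertices) - 1:
        # merging along a tree cannot create cycles; extra edges indicate
        # parallel paths collapsed onto one pair — deduplicate keeps tree
        raise AssertionError("junction merge broke the tree invariant")
    return out


def default_merge_radius(graph: SkeletonGraph) -> float:
    """Scale-adaptive junction merge radius: twice the mean MST edge length."""
    if not graph.edges:
        return 0.0
    return 2.0 * float(np.mean([w for _, _, w in graph.edges]))


def _tree_path(adj, start: int, goal: int) -> list[int] | None:
    """Unique simple path between two vertices of a tree (DFS)."""
    stack = [(start, -1)]
    parent = {start: -1}
    while stack:
        v, p = stack.pop()
        if v == goal:
            break
        for u, _ in adj[v]:
            if u != p and u not in parent:
                parent[u] = v
                stack.append((u, v))
    if goal not in parent:
        return None
    path = [goal]
    while path[-1] != start:
        path.append(parent[path[-1]])
    return path[::-1]


def split_segments(graph: SkeletonGraph) -> list[SkeletonSegment]:
    """Split the skeleton tree into node-to-node segments.

    Branches first: each endpoint (degree 1) is connected by Dijkstra's
    shortest path — on a tree, the unique path — to its geodesically nearest
    junction; interior vertices of that path are consumed. Junction-junction
    trunks are then read off the remaining adjacency. Every non-node vertex
    appears in exactly one segment; node vertices are shared.
    """
    n = len(graph.vertices)
    deg = graph.degree
    endpoints = list(np.flatnonzero(deg == 1))
    junctions = set(np.flatnonzero(deg >= 3))
    adj = graph.adjacency()

    if n == 1 or not graph.edges:
        return []

    segments: list[SkeletonSegment] = []

    if not junctions:
        # single chain: the two endpoints pair with each other
        start = min(endpoints)
        goal = max(endpoints)
        path = _tree_path(adj, start, goal)
        segments.append(
            SkeletonSegment(
                vertex_indices=path,
                points=graph.vertices[path],
                start_kind=NodeKind.ENDPOINT,
                end_kind=NodeKind.ENDPOINT,
            )
        )
        return segments

    gd = _geodesic_distances(graph, np.asarray(sorted(junctions)))
    jlist = sorted(junctions)

    consumed = np.zeros(n, dtype=bool)
    for ep in sorted(endpoints):
        dists = gd[:, ep]
        order = np.lexsort((jlist, dists))  # nearest junction, lowest index on ties
        target = jlist[order[0]]
        path = _tree_path(adj, ep, target)
        assert path is not None, "tree is connected"
        for v in path[1:-1]:
            consumed[v] = True
        consumed[ep] = True
        segments.append(
            SkeletonSegment(
                vertex_indices=path,
                points=graph.vertices[path],
                start_kind=NodeKind.ENDPOINT,
                end_kind=NodeKind.JUNCTION,
            )
        )

    # trunks: walk the unconsumed degree-2 chains between junctions
    visited_edges = set()
    for j in jlist:
        for u, _ in sorted(adj[j]):
            if (j, u) in visited_edges:
                continue
            if consumed[u] and u not in junctions:
                continue
            # walk from j through u until the next node
            path = [j, u]
            visited_edges.add((j, u))
            visited_edges.add((u, j))
            prev, cur = j, u
            while cur not in junctions and deg[cur] == 2:
                nxt = [v for v, _ in adj[cur] if v != prev][0]
                visited_edges.add((cur, nxt))
                visited_edges.add((nxt, cur))
                prev, cur = cur, nxt
                path.append(cur)
            if cur in junctions:
                for v in path[1:-1]:
                    consumed[v] = True
                segments.append(
                    SkeletonSegment(
                        vertex_indices=path,
                        points=graph.vertices[path],
                        start_kind=NodeKind.JUNCTION,
                        end_kind=NodeKind.JUNCTION,
                    )
                )
    return segments
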