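"""Octree nearest-neighbour assignment of orthotropic axis triads.

CT-derived orientation data arrive as a point cloud in which every point
carries an orthonormal triad of material axes.  Each integration point of a
mesh must receive the triad of its nearest cloud point.  A brute-force scan
costs N distance evaluations per query; the octree recursively splits the
bounding cube into eight congruent octants until every leaf holds at most
``capacity`` points, and the search prunes subtrees whose box distance
exceeds the current best — the exhaustive scan is retained as the
correctness oracle, and efficiency is asserted by counting distance
evaluations rather than by timing.

Determinism: ties at exactly equal distance resolve to the smallest cloud
index, points lying on an internal splitting plane belong to the lower
octant (half-open boxes), and the recursion depth is capped at 21 so
degenerate (duplicate-point) clouds terminate, allowing leaf overflow at
the cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import ParameterError

__all__ = [
    "OrientationCloud",
    "OctreeNode",
    "Octree",
    "QuerySet",
    "SearchStats",
    "build_octree",
    "query_nearest",
    "brute_force_nearest",
    "assign_axes",
    "orthonormalize_triad",
]

MAX_DEPTH = 21

_CLOUD_COLUMNS = ["x", "y", "z"] + [f"a{i}{c}" for i in (1, 2, 3) for c in "xyz"]


@dataclass
class OrientationCloud:
    """N points (mm) with attached right-handed orthonormal axis triads.

    ``triads[k]`` is a 3x3 matrix whose rows are material axes 1, 2, 3 of
    point k, orthonormal within 1e-8 with determinant +1.
    """

    points: np.ndarray
    triads: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.triads = np.asarray(self.triads, dtype=float).reshape(-1, 3, 3)
        n = len(self.points)
        if n < 1 or len(self.triads) != n:
            raise ParameterError("need N >= 1 points with one triad each")
        if not np.all(np.isfinite(self.points)):
            raise ParameterError("non-finite point coordinates")
        gram = np.einsum("kij,klj->kil", self.triads, self.triads)
        if not np.allclose(gram, np.eye(3), atol=1e-8):
            raise ParameterError("triads must be orthonormal within 1e-8")
        if not np.allclose(np.linalg.det(self.triads), 1.0, atol=1e-8):
            raise ParameterError("triads must be right-handed (det = +1)")

    def __len__(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        data = np.hstack([self.points, self.triads.reshape(-1, 9)])
        return pd.DataFrame(data, columns=_CLOUD_COLUMNS)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "OrientationCloud":
        df = pd.read_csv(path)
        pts = df[["x", "y", "z"]].to_numpy()
        triads = df[_CLOUD_COLUMNS[3:]].to_numpy().reshape(-1, 3, 3)
        return cls(pts, triads)


@dataclass
class QuerySet:
    """M integration-point positions (mm)."""

    positions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.positions)):
            raise ParameterError("non-finite query coordinates")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class OctreeNode:
    """Axis-aligned cubic node: leaf (point indices) or eight children."""

    corner: np.ndarray
    edge: float
    depth: int
    children: list["OctreeNode | None"] | None = None
    point_indices: np.ndarray | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class SearchStats:
    """Counts point-distance evaluations (the algorithmic cost measure)."""

    evaluations: int = 0


@dataclass
class Octree:
    """Built octree over an orientation cloud."""

    cloud: OrientationCloud
    root: OctreeNode
    capacity: int

    def leaves(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                yield node
            else:
                stack.extend(c for c in node.children if c is not None)


def build_octree(cloud: OrientationCloud, capacity: int = 8) -> Octree:
    """Build the octree; the root is the tight bounding cube of the points.

    Leaves hold at most ``capacity`` points except when the depth cap (21)
    forces overflow on degenerate clouds.
    """
    if capacity < 1:
        raise ParameterError("capacity must be >= 1")
    pts = cloud.points
    lo = pts.min(axis=0)
    edge = float((pts.max(axis=0) - lo).max())

    def split(indices: np.ndarray, corner: np.ndarray, edge: float, depth: int) -> OctreeNode:
        if len(indices) <= capacity or depth >= MAX_DEPTH or edge == 0.0:
            return OctreeNode(corner, edge, depth, point_indices=indices)
        center = corner + 0.5 * edge
        # strict > sends plane points to the lower octant (half-open boxes)
        bits = (pts[indices] > center).astype(int)
        child_of = bits[:, 0] + 2 * bits[:, 1] + 4 * bits[:, 2]
        children: list[OctreeNode | None] = [None] * 8
        half = 0.5 * edge
        for c in range(8):
            sub = indices[child_of == c]
            if len(sub) == 0:
                continue
            offs = np.array([c & 1, (c >> 1) & 1, (c >> 2) & 1], dtype=float)
            children[c] = split(sub, corner + offs * half, half, depth + 1)
        return OctreeNode(corner, edge, depth, children=children)

    root = split(np.arange(len(pts)), lo.astype(float), edge, 0)
    return Octree(cloud=cloud, root=root, capacity=capacity)


def _box_dist2(corner: np.ndarray, edge: float, q: np.ndarray) -> float:
    d = np.clip(q, corner, corner + edge) - q
    return float(d @ d)


def query_nearest(tree: Octree, q: np.ndarray, stats: SearchStats | None = None) -> int:
    """Index of the cloud point nearest to q (ties: smallest index).

    Subtrees whose bounding-box distance exceeds the current best squared
    distance are pruned; boxes at exactly the best distance are still
    visited so the smallest-index tie rule matches the brute-force oracle.
    """
    q = np.asarray(q, dtype=float).reshape(3)
    pts = tree.cloud.points
    best_d2 = np.inf
    best_idx = -1

    def visit(node: OctreeNode) -> None:
        nonlocal best_d2, best_idx
        if node.is_leaf:
            idx = node.point_indices
            d2 = np.sum((pts[idx] - q) ** 2, axis=1)
            if stats is not None:
                stats.evaluations += len(idx)
            m = d2.min()
            if m < best_d2 or (m == best_d2 and idx[d2 == m].min() < best_idx):
                best_d2 = m
                best_idx = int(idx[d2 == m].min())
            return
        order = sorted(
            (c for c in node.children if c is not None),
            key=lambda c: _box_dist2(c.corner, c.edge, q),
        )
        for child in order:
            if _box_dist2(child.corner, child.edge, q) > best_d2:
                continue
            visit(child)

    visit(tree.root)
    return best_idx


def brute_force_nearest(
    cloud: OrientationCloud, q: np.ndarray, stats: SearchStats | None = None
) -> int:
    """Linear-scan argmin of squared distance; the correctness oracle.

    Evaluates exactly N distances; ties resolve to the smallest index.
    """
    q = np.asarray(q, dtype=float).reshape(3)
    d2 = np.sum((cloud.points - q) ** 2, axis=1)
    if stats is not None:
        stats.evaluations += len(d2)
    return int(np.flatnonzero(d2 == d2.min())[0])


def orthonormalize_triad(raw: np.ndarray) -> np.ndarray:
    """Nearest orthonormal matrix (polar factor), forced to det +1.

    A det = -1 polar factor has its third axis (row) flipped, preserving the
    first two axes.  Singular input is rejected.
    """
    raw = np.asarray(raw, dtype=float).reshape(3, 3)
    U, s, Vt = np.linalg.svd(raw)
    if s[-1] <= 1e-12 * max(s[0], 1.0):
        raise ParameterError("singular triad cannot be orthonormalized")
    Q = U @ Vt
    if np.linalg.det(Q) < 0:
        Q = Q.copy()
        Q[2] = -Q[2]
    return Q


def assign_axes(
    queries: QuerySet | np.ndarray,
    cloud: OrientationCloud,
    capacity: int = 8,
    stats: SearchStats | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign to each query the triad of its nearest cloud point.

    Returns (triads (M,3,3), source indices (M,), distances (M,)).  Triads
    are re-orthonormalized before being emitted, so every output is a
    rotation matrix even if the stored cloud triads carry rounding noise.
    """
    if not isinstance(queries, QuerySet):
        queries = QuerySet(queries)
    tree = build_octree(cloud, capacity)
    m = len(queries)
    triads = np.empty((m, 3, 3))
    indices = np.empty(m, dtype=int)
    dists = np.empty(m)
    for k, q in enumerate(queries.positions):
        i = query_nearest(tree, q, stats)
        indices[k] = i
        dists[k] = float(np.linalg.norm(cloud.points[i] - q))
        triads[k] = orthonormalize_triad(cloud.triads[i])
    return triads, indices, dists
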