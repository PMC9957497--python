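"""Projection of data points onto embedding trees.

The projection of a point ``x`` onto a tree is its nearest point on the
union of edge segments.  For a single segment ``[y_j, y_k]`` the nearest
point is available in closed form: the segment parameter is

    l = clip(<x - y_j, y_k - y_j> / ||y_k - y_j||^2, 0, 1)

and the projection is ``y_j + l (y_k - y_j)``.  The tree projection is the
best edge projection over all edges.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .tree import Dataset, Edge, EmbeddingTree, validate_tree

__all__ = [
    "ProjectionResult",
    "ProjectionArrays",
    "project_to_edge",
    "project_to_tree",
    "project_all",
    "project_points",
    "segment_sq_distances",
]

# squared-length threshold below which an edge is treated as degenerate
_DEGENERATE_SQ = 1e-300


def project_to_edge(x: np.ndarray, yj: np.ndarray, yk: np.ndarray):
    """Project ``x`` onto the segment ``[yj, yk]``.

    Returns ``(l, phi, sq_dist)``.  A zero-length edge (coincident
    endpoints) uses the convention ``l = 0``, ``phi = yj``, which keeps
    the distance continuous as an edge collapses.
    """
    x = np.asarray(x, dtype=float)
    yj = np.asarray(yj, dtype=float)
    yk = np.asarray(yk, dtype=float)
    if not (x.shape == yj.shape == yk.shape):
        raise ValueError("x, yj, yk must share a dimension")
    d = yk - yj
    denom = float(d @ d)
    if denom <= _DEGENERATE_SQ:
        l = 0.0
    else:
        l = float(np.clip((x - yj) @ d / denom, 0.0, 1.0))
    phi = yj + l * d
    diff = x - phi
    return l, phi, float(diff @ diff)


@dataclasses.dataclass(frozen=True)
class ProjectionResult:
    """Nearest point of one cell on a tree."""

    point: np.ndarray      # phi_T(x)
    edge: Edge             # arg-min edge (canonical order)
    l: float               # segment parameter in [0, 1]
    sq_residual: float     # ||x - phi_T(x)||^2


@dataclasses.dataclass(frozen=True)
class ProjectionArrays:
    """Vectorized projection of many cells; row ``i`` describes cell ``i``."""

    edge_index: np.ndarray  # (n,) int, index into tree.edges
    l: np.ndarray           # (n,)
    points: np.ndarray      # (n, p)
    sq_residual: np.ndarray # (n,)

    def result(self, tree: EmbeddingTree, i: int) -> ProjectionResult:
        e = tree.edges[int(self.edge_index[i])]
        return ProjectionResult(self.points[i].copy(), e,
                                float(self.l[i]), float(self.sq_residual[i]))


def segment_sq_distances(X: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Clamped parameters and squared distances from rows of ``X`` to
    segment ``[a, b]``.  Returns ``(l, sq)`` with shapes ``(n,)``."""
    d = b - a
    denom = float(d @ d)
    Xa = X - a
    if denom <= _DEGENERATE_SQ:
        l = np.zeros(X.shape[0])
        sq = np.einsum("ij,ij->i", Xa, Xa)
        return l, sq
    l = np.clip(Xa @ d / denom, 0.0, 1.0)
    diff = Xa - l[:, None] * d
    return l, np.einsum("ij,ij->i", diff, diff)


def project_points(X: np.ndarray, tree: EmbeddingTree,
                   check: bool = True) -> ProjectionArrays:
    """Project every row of ``X`` onto ``tree`` (vectorized).

    Ties between equidistant edges resolve to the smallest canonical edge
    (``tree.edges`` is canonically sorted and ``argmin`` keeps the first),
    so results are deterministic.
    """
    X = np.asarray(X, dtype=float)
    if check and not validate_tree(tree):
        raise ValueError("invalid tree")
    if X.shape[1] != tree.dimension:
        raise ValueError(
            f"dimension mismatch: data has p={X.shape[1]}, tree has p={tree.dimension}")
    y = tree.embedding
    n = X.shape[0]
    n_e = len(tree.edges)
    L = np.empty((n_e, n))
    SQ = np.empty((n_e, n))
    for idx, (j, k) in enumerate(tree.edges):
        L[idx], SQ[idx] = segment_sq_distances(X, y[j], y[k])
    best = np.argmin(SQ, axis=0)
    rows = np.arange(n)
    l = L[best, rows]
    sq = SQ[best, rows]
    ej = np.array([tree.edges[i][0] for i in best])
    ek = np.array([tree.edges[i][1] for i in best])
    points = y[ej] + l[:, None] * (y[ek] - y[ej])
    return ProjectionArrays(best, l, points, sq)


def project_to_tree(x: np.ndarray, tree: EmbeddingTree) -> ProjectionResult:
    """Nearest point on the tree to a single point ``x``."""
    arrays = project_points(np.asarray(x, dtype=float)[None, :], tree)
    return arrays.result(tree, 0)


def project_all(data: Dataset, tree: EmbeddingTree) -> list[ProjectionResult]:
    """Per-cell :class:`ProjectionResult` list (elementwise
    :func:`project_to_tree`)."""
    arrays = project_points(data.X, tree)
    return [arrays.result(tree, i) for i in range(data.n)]
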