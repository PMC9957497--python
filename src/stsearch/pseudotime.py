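"""Pseudotime as shortest-path distance along a fitted tree.

Each edge is weighted by the Euclidean distance between its vertex
coordinates, and each cell's pseudotime is the length of the (unique)
path along the tree from a chosen origin to the cell's projection point.
Cells are then ordered by increasing pseudotime.

The origin may be a tree vertex or a cell (whose projection onto the tree
becomes the origin point).  The method itself does not identify the
biological starting state; the origin encodes prior knowledge (e.g. a
known progenitor cell).
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .projection import project_points
from .tree import Dataset, Edge, EmbeddingTree, canonical_edge, tree_edge_lengths

__all__ = [
    "TreePoint",
    "PseudotimeResult",
    "tree_geodesic",
    "compute_pseudotime",
    "suggest_origin",
    "kendall_correlation",
]

# a point on a tree: (canonical edge, parameter l in [0, 1])
TreePoint = tuple[Edge, float]


def _as_graph(tree: EmbeddingTree) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(tree.vertices)
    for e, w in tree_edge_lengths(tree).items():
        g.add_edge(*e, weight=w)
    return g


def _check_point(tree: EmbeddingTree, pt: TreePoint) -> tuple[Edge, float]:
    edge, l = pt
    edge = canonical_edge(*edge)
    if edge not in tree.edges:
        raise ValueError(f"point references edge {edge} not in tree")
    if not (0.0 <= l <= 1.0) or not np.isfinite(l):
        raise ValueError("segment parameter must lie in [0, 1]")
    return edge, float(l)


def _point_to_vertex_distances(tree: EmbeddingTree, pt: TreePoint,
                               lengths: dict[Edge, float],
                               vertex_dist: dict[int, dict[int, float]]
                               ) -> dict[int, float]:
    """Geodesic distance from an on-tree point to every vertex."""
    (j, k), l = pt
    length = lengths[(j, k)]
    return {
        v: min(l * length + vertex_dist[j][v], (1.0 - l) * length + vertex_dist[k][v])
        for v in tree.vertices
    }


def tree_geodesic(tree: EmbeddingTree, a: TreePoint, b: TreePoint) -> float:
    """Length of the unique path along the tree between two on-tree
    points given as ``(edge, l)`` pairs."""
    a = _check_point(tree, a)
    b = _check_point(tree, b)
    lengths = tree_edge_lengths(tree)
    if a[0] == b[0]:
        return abs(a[1] - b[1]) * lengths[a[0]]
    g = _as_graph(tree)
    vd = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    da = _point_to_vertex_distances(tree, a, lengths, vd)
    (j, k), l = b
    length = lengths[(j, k)]
    return min(l * length + da[j], (1.0 - l) * length + da[k])


@dataclasses.dataclass
class PseudotimeResult:
    """Per-cell pseudotimes from a fixed origin, plus the induced cell
    ordering (ties broken by cell id)."""

    pseudotime: dict[str, float]
    origin: int | str
    order: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "cell_id": self.order,
            "pseudotime": [self.pseudotime[c] for c in self.order],
        })
        df["rank"] = np.arange(len(df))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def values_for(self, cell_ids) -> np.ndarray:
        return np.array([self.pseudotime[c] for c in cell_ids])


def compute_pseudotime(data: Dataset, tree: EmbeddingTree,
                       origin: int | str | TreePoint) -> PseudotimeResult:
    """Pseudotime of every cell from ``origin``.

    The origin may be a tree vertex id (``int``), a cell id (``str``,
    whose projection becomes the origin point), or an explicit on-tree
    point ``(edge, l)``."""
    proj = project_points(data.X, tree)
    lengths = tree_edge_lengths(tree)
    g = _as_graph(tree)
    vd = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))

    if isinstance(origin, tuple):
        origin_pt: TreePoint = _check_point(tree, origin)
    elif isinstance(origin, (int, np.integer)):
        if origin not in range(tree.n_vertices):
            raise ValueError(f"origin vertex {origin} not in tree")
        # any incident edge represents the vertex as an on-tree point
        inc = tree.incident_edge_indices(int(origin))
        edge = tree.edges[inc[0]]
        origin_pt = (edge, 0.0 if edge[0] == origin else 1.0)
    elif isinstance(origin, str):
        if origin not in data.cell_ids:
            raise ValueError(f"origin cell {origin!r} not in dataset")
        i = data.cell_ids.index(origin)
        origin_pt = (tree.edges[int(proj.edge_index[i])], float(proj.l[i]))
    else:
        raise TypeError("origin must be a vertex id (int) or cell id (str)")

    d_origin = _point_to_vertex_distances(tree, origin_pt, lengths, vd)
    o_edge, o_l = origin_pt
    o_len = lengths[o_edge]

    pt: dict[str, float] = {}
    for i, cell in enumerate(data.cell_ids):
        edge = tree.edges[int(proj.edge_index[i])]
        l = float(proj.l[i])
        if edge == o_edge:
            pt[cell] = abs(l - o_l) * o_len
        else:
            j, k = edge
            length = lengths[edge]
            pt[cell] = min(l * length + d_origin[j],
                           (1.0 - l) * length + d_origin[k])
    order = sorted(data.cell_ids, key=lambda c: (pt[c], c))
    return PseudotimeResult(pt, origin, order)


def suggest_origin(data: Dataset, tree: EmbeddingTree,
                   feature: int = 0) -> int:
    """Heuristic origin: the leaf vertex nearest to the cell with the
    smallest value of the given feature (column of the reduced space).

    Purely a convenience for exploratory use — the origin encodes
    biological knowledge the data alone cannot supply, so prefer passing
    a known starting vertex or cell explicitly.
    """
    if not (0 <= feature < data.p):
        raise ValueError(f"feature index {feature} out of range")
    cell = int(np.argmin(data.X[:, feature]))
    leaves = tree.leaves()
    dists = [float(np.linalg.norm(tree.embedding[v] - data.X[cell]))
             for v in leaves]
    return leaves[int(np.argmin(dists))]


def kendall_correlation(estimated, truth) -> float:
    """Kendall's tau-b between two pseudotime assignments.

    Tau-b corrects for ties, which occur whenever several cells project
    to the same tree point.  Constant input on either side leaves the
    coefficient undefined and raises ``ValueError``.
    """
    est = np.asarray(estimated, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if est.shape != tru.shape or est.ndim != 1 or est.size < 2:
        raise ValueError("inputs must be equal-length 1-D arrays with n >= 2")
    if np.all(est == est[0]) or np.all(tru == tru[0]):
        raise ValueError("Kendall correlation undefined for constant input")
    tau = stats.kendalltau(est, tru).statistic
    return float(tau)
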