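"""Embedding-based distance between two same-size trees.

Used by the stochastic search to keep its candidate pool diverse: a
candidate too close to an existing pool member (score below the cutoff
``a``) is not admitted.  Despite the customary name "similarity score",
larger values mean *more different* trees — the score is zero for
identical trees and grows with geometric discrepancy.

The score has a vertex part and an edge part, both nearest-match sums so
that identical trees score exactly zero.  The vertex part sums, over the
vertices of the first tree, the distance to the nearest vertex of the
second tree (directional; symmetry is not required).  The edge part sums,
over the edges of the first tree, the discrepancy to the nearest edge of
the second tree, where the discrepancy of an edge pair (i, j) is
sqrt(d1^2 + d2^2) with d1 (d2) the distance from the first (second)
endpoint of edge i to the nearest endpoint of edge j.  No combinatorial
matching of topologies is involved; the score is purely geometric.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .tree import EmbeddingTree

__all__ = ["vertex_set_distance", "edge_set_distance", "tree_similarity"]


def _check_sizes(t1: EmbeddingTree, t2: EmbeddingTree) -> None:
    if t1.n_vertices != t2.n_vertices:
        raise ValueError(
            f"trees must have equal size ({t1.n_vertices} != {t2.n_vertices})")


def vertex_set_distance(t1: EmbeddingTree, t2: EmbeddingTree) -> float:
    """Sum over vertices of ``t1`` of the distance to the nearest vertex
    of ``t2``."""
    _check_sizes(t1, t2)
    d = cdist(t1.embedding, t2.embedding)
    return float(d.min(axis=1).sum())


def edge_set_distance(t1: EmbeddingTree, t2: EmbeddingTree) -> float:
    """Sum over edges of ``t1`` of the endpoint-to-nearest-endpoint
    discrepancy sqrt(d1^2 + d2^2) to the nearest edge of ``t2``."""
    _check_sizes(t1, t2)
    d = cdist(t1.embedding, t2.embedding)  # vertex-to-vertex distances
    e1 = np.asarray(t1.edges)  # (s-1, 2)
    e2 = np.asarray(t2.edges)
    # d1[i, j] = min distance from first endpoint of edge i (t1) to either
    # endpoint of edge j (t2); d2 likewise for the second endpoint
    d1 = np.minimum(d[np.ix_(e1[:, 0], e2[:, 0])], d[np.ix_(e1[:, 0], e2[:, 1])])
    d2 = np.minimum(d[np.ix_(e1[:, 1], e2[:, 0])], d[np.ix_(e1[:, 1], e2[:, 1])])
    return float(np.sqrt(d1 ** 2 + d2 ** 2).min(axis=1).sum())


def tree_similarity(t1: EmbeddingTree, t2: EmbeddingTree) -> float:
    """Total tree discrepancy: vertex part plus edge part.

    Zero iff the two vertex clouds and edge endpoint geometries coincide.
    Pool admission always calls this as ``tree_similarity(candidate,
    pool_member)``; the score is not guaranteed symmetric.
    """
    return vertex_set_distance(t1, t2) + edge_set_distance(t1, t2)
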