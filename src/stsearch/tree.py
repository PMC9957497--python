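"""Core domain types: embedding trees, datasets and configuration.

An *embedding tree* ``T = (V, E, y)`` is a connected acyclic graph whose
vertices carry coordinates ``y_j`` in ``R^p`` (the dimension-reduced
expression space).  Edges are straight line segments between vertex
coordinates; the tree is the geometric object that single-cell trajectory
fitting optimizes.  Vertices are dense integers ``0..|V|-1`` and edges are
stored as sorted ``(min, max)`` pairs so that equality is canonical.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Sequence

import numpy as np

Edge = tuple[int, int]

__all__ = [
    "Edge",
    "EmbeddingTree",
    "Dataset",
    "STSConfig",
    "canonical_edge",
    "validate_tree",
    "tree_diagnostics",
    "tree_edge_lengths",
]


def canonical_edge(j: int, k: int) -> Edge:
    """Return the canonical ``(min, max)`` form of an undirected edge."""
    return (j, k) if j <= k else (k, j)


@dataclasses.dataclass(frozen=True)
class EmbeddingTree:
    """A tree with vertex coordinates in ``R^p``.

    Parameters
    ----------
    embedding
        Array of shape ``(|V|, p)``; row ``j`` is the coordinate of vertex
        ``j``.
    edges
        ``|V| - 1`` unordered vertex-id pairs.  Stored canonically sorted.
    """

    embedding: np.ndarray
    edges: tuple[Edge, ...]

    def __post_init__(self) -> None:
        emb = np.asarray(self.embedding, dtype=float)
        if emb.ndim != 2:
            raise ValueError("embedding must be a 2-D array of shape (|V|, p)")
        object.__setattr__(self, "embedding", emb)
        canon = tuple(sorted(canonical_edge(int(j), int(k)) for j, k in self.edges))
        object.__setattr__(self, "edges", canon)

    # -- basic accessors -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return self.embedding.shape[0]

    @property
    def dimension(self) -> int:
        return self.embedding.shape[1]

    @property
    def vertices(self) -> tuple[int, ...]:
        return tuple(range(self.n_vertices))

    def neighbors(self, v: int) -> list[int]:
        """Vertices adjacent to ``v``."""
        out = []
        for j, k in self.edges:
            if j == v:
                out.append(k)
            elif k == v:
                out.append(j)
        return out

    def leaves(self) -> list[int]:
        deg = np.zeros(self.n_vertices, dtype=int)
        for j, k in self.edges:
            deg[j] += 1
            deg[k] += 1
        return [int(v) for v in np.nonzero(deg == 1)[0]]

    def incident_edge_indices(self, v: int) -> list[int]:
        return [i for i, (j, k) in enumerate(self.edges) if v in (j, k)]

    # -- functional updates ----------------------------------------------
    def with_vertex_moved(self, v: int, y: np.ndarray) -> "EmbeddingTree":
        """A copy of the tree with vertex ``v`` relocated to ``y``."""
        y = np.asarray(y, dtype=float)
        if y.shape != (self.dimension,):
            raise ValueError(f"coordinate must have shape ({self.dimension},)")
        emb = self.embedding.copy()
        emb[v] = y
        return EmbeddingTree(emb, self.edges)

    def copy(self) -> "EmbeddingTree":
        return EmbeddingTree(self.embedding.copy(), self.edges)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "vertices": list(self.vertices),
            "edges": [list(e) for e in self.edges],
            "embedding": self.embedding.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EmbeddingTree":
        return cls(np.asarray(d["embedding"], dtype=float),
                   tuple((int(j), int(k)) for j, k in d["edges"]))

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict())
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "EmbeddingTree":
        """Load a tree from a JSON string or a path to a JSON file."""
        s = str(source)
        if s.lstrip().startswith("{"):
            return cls.from_dict(json.loads(s))
        with open(source) as fh:
            return cls.from_dict(json.load(fh))

    def adjacency_matrix(self) -> np.ndarray:
        """Dense ``|V| x |V|`` matrix of Euclidean edge lengths (0 = no edge)."""
        A = np.zeros((self.n_vertices, self.n_vertices))
        for (j, k), length in tree_edge_lengths(self).items():
            A[j, k] = A[k, j] = length
        return A

    def adjacency_to_csv(self, path) -> None:
        np.savetxt(path, self.adjacency_matrix(), delimiter=",")


def tree_diagnostics(tree: EmbeddingTree) -> list[str]:
    """Explain every violated tree invariant; empty list means valid."""
    problems: list[str] = []
    nv = tree.n_vertices
    if nv < 1:
        problems.append("tree has no vertices")
        return problems
    if tree.dimension < 1:
        problems.append("embedding dimension must be >= 1")
    if not np.all(np.isfinite(tree.embedding)):
        problems.append("embedding contains non-finite coordinates")
    edges = tree.edges
    if len(set(edges)) != len(edges):
        problems.append("duplicate edges")
    for j, k in edges:
        if j == k:
            problems.append(f"self-loop at vertex {j}")
        if not (0 <= j < nv and 0 <= k < nv):
            problems.append(f"edge ({j},{k}) references unknown vertex")
    if problems:
        return problems
    if len(edges) != nv - 1:
        problems.append(f"|E| = {len(edges)} but |V| - 1 = {nv - 1}")
        return problems
    # connectivity by union-find; with |E| = |V|-1 and no cycles this
    # is equivalent to being a tree
    parent = list(range(nv))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for j, k in edges:
        rj, rk = find(j), find(k)
        if rj == rk:
            problems.append(f"edge ({j},{k}) closes a cycle")
            return problems
        parent[rj] = rk
    roots = {find(v) for v in range(nv)}
    if len(roots) > 1:
        problems.append("graph is disconnected")
    return problems


def validate_tree(tree: EmbeddingTree) -> bool:
    """True iff ``tree`` satisfies all embedding-tree invariants."""
    return not tree_diagnostics(tree)


def tree_edge_lengths(tree: EmbeddingTree) -> dict[Edge, float]:
    """Euclidean length of every edge, keyed by canonical edge."""
    if not validate_tree(tree):
        raise ValueError("invalid tree: " + "; ".join(tree_diagnostics(tree)))
    y = tree.embedding
    return {
        (j, k): float(np.linalg.norm(y[j] - y[k]))
        for j, k in tree.edges
    }


@dataclasses.dataclass
class Dataset:
    """Cells in the dimension-reduced space.

    ``X`` holds one row per cell.  ``sigma2_hat`` is the pooled noise
    variance estimate used by the BIC-style complexity penalty; by default
    it is the mean per-dimension sample variance of ``X``.
    """

    X: np.ndarray
    cell_ids: list[str]
    sigma2_hat: float | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (cells x dimensions)")
        n, p = self.X.shape
        if n < 2 or p < 1:
            raise ValueError("need at least 2 cells and 1 dimension")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite entries")
        if self.cell_ids is None:
            self.cell_ids = [f"cell{i}" for i in range(n)]
        if len(self.cell_ids) != n:
            raise ValueError("cell_ids length must match number of rows")
        if self.sigma2_hat is None:
            self.sigma2_hat = float(np.mean(np.var(self.X, axis=0, ddof=1)))
        if self.sigma2_hat <= 0:
            raise ValueError("sigma2_hat must be positive")

    @classmethod
    def from_array(cls, X, cell_ids: Sequence[str] | None = None) -> "Dataset":
        X = np.asarray(X, dtype=float)
        ids = list(cell_ids) if cell_ids is not None else [f"cell{i}" for i in range(X.shape[0])]
        return cls(X, ids)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def diameter(self) -> float:
        """Largest pairwise Euclidean distance between cells.

        Exact for moderate n; for very large n the bounding-box diagonal
        (an upper bound within a factor of 1) is used instead.
        """
        if self.n <= 2048:
            from scipy.spatial.distance import pdist

            return float(pdist(self.X).max())
        span = self.X.max(axis=0) - self.X.min(axis=0)
        return float(np.linalg.norm(span))


@dataclasses.dataclass
class STSConfig:
    """Hyperparameters of the stochastic tree search.

    ``lambda1`` (tree-size penalty weight) defaults to ``"auto"``: the
    BIC-derived value sigma2_hat * p * log(n).  ``similarity_cutoff_a``
    defaults to ``"auto"``: one tenth of the data diameter.
    """

    lambda1: float | str = "auto"
    lambda2: float = 0.01
    lambda3: float = 1.0
    alpha: float = 1.0
    pool_size_L1: int = 10
    grow_repeats_L2: int = 80
    similarity_cutoff_a: float | str = "auto"
    ls_shrink_p: float = 0.8
    ls_armijo_c: float = 0.5
    grad_eps: float = 1e-6
    tol: float = 1e-5
    max_tree_size: int = 30
    seed: int = 0
    # numerical safeguards (not search hyperparameters)
    max_sweeps: int = 100
    ls_max_steps: int = 50
    ls_max_shrinks: int = 60
    leaf_move_prob: float = 0.5
    admit_vs_worst: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.ls_shrink_p < 1.0):
            raise ValueError("ls_shrink_p must lie in (0, 1)")
        if not (0.0 < self.ls_armijo_c < 1.0):
            raise ValueError("ls_armijo_c must lie in (0, 1)")
        if self.grad_eps <= 0 or self.tol <= 0:
            raise ValueError("grad_eps and tol must be positive")
        for name in ("lambda2", "lambda3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if isinstance(self.lambda1, (int, float)) and self.lambda1 < 0:
            raise ValueError("lambda1 must be nonnegative")

    def resolve(self, data: Dataset) -> "STSConfig":
        """Concrete copy with ``"auto"`` values computed from the data."""
        cfg = dataclasses.replace(self)
        if cfg.lambda1 == "auto":
            from .objective import auto_lambda1

            cfg.lambda1 = auto_lambda1(data)
        if cfg.similarity_cutoff_a == "auto":
            # the nearest-match similarity score of trees fitted to the same
            # data lives on the scale of a small fraction of the data spread
            cfg.similarity_cutoff_a = 0.02 * data.diameter()
        return cfg
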