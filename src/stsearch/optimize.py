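"""Vertex-embedding updates by backtracking line search.

Given a tree topology, each vertex location is refined in turn by
minimizing

    S(y) = sum_i ||x_i - phi_T(x_i)||^2 + lambda2 * sum_{k in N(v)} ||y - y_k||^2

where the tree in the first term has vertex ``v`` moved to ``y`` and the
second term runs over the neighbors of ``v``.  Because moving ``v`` only
changes the segments incident to ``v``, the residual of each cell is the
minimum of a precomputed "distance to the rest of the tree" and its
distance to the incident segments, which makes evaluating S(y) cheap; the
evaluator also scores whole batches of candidate locations at once so the
finite-difference gradient and the step-size schedule cost one vectorized
call each.

S has no closed-form minimizer (the cell-to-edge assignment changes with
``y``), so a gradient step with a backtracking line search is used: the
gradient is a forward finite difference, the step size starts at
``tau_max = 1`` and shrinks geometrically (factor 0.8) until a sufficient
decrease condition with constant c = 0.5 holds.  Descent is guaranteed:
a vertex is only moved when S does not increase.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .projection import segment_sq_distances
from .tree import Dataset, EmbeddingTree, STSConfig, validate_tree

__all__ = [
    "vertex_objective",
    "numerical_gradient",
    "backtracking_update",
    "optimize_embedding",
]

_TINY_GRAD_SQ = 1e-18
_DEGENERATE_SQ = 1e-300
_SHRINK_CHUNK = 8  # step sizes evaluated per vectorized call

try:  # the compiled kernel makes vertex updates ~50x faster
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco


@_njit(cache=True)
def _s_one_kernel(y, A, Xa, nXa, other_sq, lambda2):
    """S at a single candidate location y (JIT-compiled)."""
    m, n, p = Xa.shape
    reg = 0.0
    d = np.empty((m, p))
    denom = np.empty(m)
    for k in range(m):
        s = 0.0
        for c in range(p):
            dc = y[c] - A[k, c]
            d[k, c] = dc
            s += dc * dc
        denom[k] = s
        reg += s
    total = 0.0
    for i in range(n):
        best = other_sq[i]
        for k in range(m):
            if denom[k] <= _DEGENERATE_SQ:
                sq = nXa[k, i]
            else:
                G = 0.0
                for c in range(p):
                    G += Xa[k, i, c] * d[k, c]
                t = G / denom[k]
                if t < 0.0:
                    t = 0.0
                elif t > 1.0:
                    t = 1.0
                sq = nXa[k, i] - 2.0 * t * G + t * t * denom[k]
            if sq < best:
                best = sq
        total += best
    return total + lambda2 * reg


@_njit(cache=True)
def _line_search_loop(y0, A, Xa, nXa, other_sq, lambda2, shrink_p, armijo_c,
                      eps, tol, max_steps, max_shrinks):
    """Full iterated backtracking line search (JIT-compiled).

    Semantics match the Python path in ``_line_search_minimize``: forward
    finite-difference gradient, geometric step shrinking from tau_max = 1,
    sufficient-decrease acceptance with guaranteed non-ascent.
    """
    p = y0.shape[0]
    y = y0.copy()
    g = np.empty(p)
    yd = np.empty(p)
    y_new = np.empty(p)
    s_cur = _s_one_kernel(y, A, Xa, nXa, other_sq, lambda2)
    for _step in range(max_steps):
        s0 = _s_one_kernel(y, A, Xa, nXa, other_sq, lambda2)
        s_cur = s0
        for c in range(p):
            for c2 in range(p):
                yd[c2] = y[c2]
            yd[c] = y[c] + eps
            g[c] = (_s_one_kernel(yd, A, Xa, nXa, other_sq, lambda2) - s0) / eps
        gg = 0.0
        for c in range(p):
            gg += g[c] * g[c]
        if not np.isfinite(gg):
            raise FloatingPointError("non-finite objective in gradient evaluation")
        if gg <= _TINY_GRAD_SQ:
            break
        tau = 1.0
        accepted = False
        s_new = s0
        for _b in range(max_shrinks):
            tau *= shrink_p
            for c in range(p):
                y_new[c] = y[c] - tau * g[c]
            s_new = _s_one_kernel(y_new, A, Xa, nXa, other_sq, lambda2)
            if s_new - s0 <= armijo_c * tau * gg and s_new <= s0:
                accepted = True
                break
        if not accepted:
            break
        improved = s0 - s_new
        for c in range(p):
            y[c] = y_new[c]
        s_cur = s_new
        if improved <= tol * (1.0 + abs(s_new)):
            break
    return y, s_cur


@_njit(cache=True)
def _s_batch_kernel(Y, A, Xa, nXa, other_sq, lambda2, out):
    """S at each candidate row of Y; loops are JIT-compiled."""
    q, p = Y.shape
    m = A.shape[0]
    n = other_sq.shape[0]
    d = np.empty((m, p))
    denom = np.empty(m)
    for iq in range(q):
        reg = 0.0
        for k in range(m):
            s = 0.0
            for c in range(p):
                dc = Y[iq, c] - A[k, c]
                d[k, c] = dc
                s += dc * dc
            denom[k] = s
            reg += s
        total = 0.0
        for i in range(n):
            best = other_sq[i]
            for k in range(m):
                if denom[k] <= _DEGENERATE_SQ:
                    sq = nXa[k, i]
                else:
                    G = 0.0
                    for c in range(p):
                        G += Xa[k, i, c] * d[k, c]
                    t = G / denom[k]
                    if t < 0.0:
                        t = 0.0
                    elif t > 1.0:
                        t = 1.0
                    sq = nXa[k, i] - 2.0 * t * G + t * t * denom[k]
                if sq < best:
                    best = sq
            total += best
        out[iq] = total + lambda2 * reg


class _VertexProblem:
    """Fast evaluator of S(y) for a single movable vertex.

    ``other_sq[i]`` caches each cell's squared distance to the edges *not*
    incident to the vertex; only the incident segments are recomputed per
    evaluation.  For a batch of q candidate locations Y the squared
    distance of cell i to segment [a, Y_q] is expanded as

        ||x_i - a||^2 - 2 t G + t^2 ||Y_q - a||^2,   G = <x_i - a, Y_q - a>

    with t = clip(G / ||Y_q - a||^2, 0, 1), which needs one (n x q)
    matrix product per neighbor.
    """

    def __init__(self, tree: EmbeddingTree, vertex: int, data: Dataset,
                 cfg: STSConfig, other_sq: np.ndarray | None = None):
        if vertex not in range(tree.n_vertices):
            raise ValueError(f"vertex {vertex} not in tree")
        X = data.X
        self.lambda2 = cfg.lambda2
        self.neighbor_coords = np.ascontiguousarray(
            tree.embedding[tree.neighbors(vertex)])
        # per-neighbor precomputation: X - a and its squared norms
        self._Xa = np.ascontiguousarray(X[None, :, :] - self.neighbor_coords[:, None, :])
        self._nXa = np.einsum("kij,kij->ki", self._Xa, self._Xa)
        if other_sq is None:
            y = tree.embedding
            other = [
                segment_sq_distances(X, y[j], y[k])[1]
                for (j, k) in tree.edges if vertex not in (j, k)
            ]
            other_sq = (np.minimum.reduce(other) if other
                        else np.full(X.shape[0], np.inf))
        self.other_sq = other_sq

    def batch(self, Y: np.ndarray) -> np.ndarray:
        """S at each row of ``Y``; shape (q,)."""
        Y = np.ascontiguousarray(np.atleast_2d(Y))
        if _HAVE_NUMBA:
            out = np.empty(Y.shape[0])
            _s_batch_kernel(Y, self.neighbor_coords, self._Xa, self._nXa,
                            self.other_sq, self.lambda2, out)
            return out
        return self._batch_numpy(Y)

    def _batch_numpy(self, Y: np.ndarray) -> np.ndarray:
        q = Y.shape[0]
        best = np.broadcast_to(self.other_sq[:, None], (self.other_sq.size, q)).copy()
        reg = np.zeros(q)
        for a, Xa, nXa in zip(self.neighbor_coords, self._Xa, self._nXa):
            d = Y - a                       # (q, p)
            denom = np.einsum("ij,ij->i", d, d)  # (q,)
            G = Xa @ d.T                    # (n, q)
            safe = np.maximum(denom, _DEGENERATE_SQ)
            t = G / safe
            np.clip(t, 0.0, 1.0, out=t)
            t[:, denom <= _DEGENERATE_SQ] = 0.0
            sq = nXa[:, None] - 2.0 * t * G + t * t * denom
            np.minimum(best, sq, out=best)
            reg += self.lambda2 * denom
        return best.sum(axis=0) + reg

    def __call__(self, y: np.ndarray) -> float:
        return float(self.batch(np.asarray(y, dtype=float)[None, :])[0])


def vertex_objective(y: np.ndarray, vertex: int, tree: EmbeddingTree,
                     data: Dataset, cfg: STSConfig) -> float:
    """S(y): penalized residual sum with ``vertex`` relocated to ``y``."""
    return _VertexProblem(tree, vertex, data, cfg)(np.asarray(y, dtype=float))


def numerical_gradient(y: np.ndarray, S: Callable[[np.ndarray], float],
                       eps: float = 1e-6) -> np.ndarray:
    """Forward-difference gradient: component d is (S(y + eps e_d) - S(y)) / eps."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    y = np.asarray(y, dtype=float)
    s0 = S(y)
    grad = np.empty_like(y)
    for d in range(y.size):
        yd = y.copy()
        yd[d] += eps
        grad[d] = (S(yd) - s0) / eps
    if not np.all(np.isfinite(grad)) or not np.isfinite(s0):
        raise FloatingPointError("non-finite objective in gradient evaluation")
    return grad


def _line_search_minimize(y0: np.ndarray, problem: _VertexProblem,
                          cfg: STSConfig) -> tuple[np.ndarray, float]:
    """Iterated backtracking gradient steps from ``y0``; never ascends."""
    if _HAVE_NUMBA:
        other = np.ascontiguousarray(problem.other_sq, dtype=float)
        return _line_search_loop(
            np.ascontiguousarray(y0, dtype=float), problem.neighbor_coords,
            problem._Xa, problem._nXa, other, problem.lambda2,
            cfg.ls_shrink_p, cfg.ls_armijo_c, cfg.grad_eps, cfg.tol,
            cfg.ls_max_steps, cfg.ls_max_shrinks)
    y = np.asarray(y0, dtype=float).copy()
    p_dim = y.size
    eps = cfg.grad_eps
    eye = np.eye(p_dim) * eps
    s_cur = problem(y)
    for _ in range(cfg.ls_max_steps):
        # batched forward-difference gradient: S at y and y + eps e_d
        vals = problem.batch(np.vstack([y[None, :], y + eye]))
        if not np.all(np.isfinite(vals)):
            raise FloatingPointError("non-finite objective in gradient evaluation")
        s_cur = float(vals[0])
        g = (vals[1:] - s_cur) / eps
        gg = float(g @ g)
        if gg <= _TINY_GRAD_SQ:
            break
        accepted = False
        shrinks = cfg.ls_shrink_p ** np.arange(1, cfg.ls_max_shrinks + 1)
        for start in range(0, cfg.ls_max_shrinks, _SHRINK_CHUNK):
            taus = shrinks[start:start + _SHRINK_CHUNK]
            cand = y[None, :] - taus[:, None] * g[None, :]
            s_cand = problem.batch(cand)
            # sufficient-decrease test; the extra <= s_cur clause enforces
            # monotone descent even where S is kinked
            ok = (s_cand - s_cur <= cfg.ls_armijo_c * taus * gg) & (s_cand <= s_cur)
            hits = np.nonzero(ok)[0]
            if hits.size:
                i = int(hits[0])
                y_new, s_new = cand[i], float(s_cand[i])
                accepted = True
                break
        if not accepted:
            break
        improved = s_cur - s_new
        y, s_cur = y_new, s_new
        if improved <= cfg.tol * (1.0 + abs(s_cur)):
            break
    return y, s_cur


def backtracking_update(vertex: int, tree: EmbeddingTree, data: Dataset,
                        cfg: STSConfig) -> EmbeddingTree:
    """Move one vertex to the location found by the backtracking line
    search.  The returned tree never has a larger S than the input."""
    problem = _VertexProblem(tree, vertex, data, cfg)
    y0 = tree.embedding[vertex]
    y_star, s_star = _line_search_minimize(y0, problem, cfg)
    if s_star > problem(y0):
        return tree
    return tree.with_vertex_moved(vertex, y_star)


def optimize_embedding(tree: EmbeddingTree, data: Dataset, cfg: STSConfig,
                       return_trace: bool = False):
    """Sweep line-search updates over all vertices until the penalized
    objective stabilizes.

    Vertices are visited in ascending id order each sweep (deterministic).
    The trace, if requested, records the total objective after every
    vertex update; it is monotone non-increasing by construction.
    """
    if not validate_tree(tree):
        raise ValueError("invalid tree")
    cfg = cfg.resolve(data) if (cfg.lambda1 == "auto"
                                or cfg.similarity_cutoff_a == "auto") else cfg
    work = tree.copy()
    emb = work.embedding  # mutated in place between rebuilds
    X = data.X
    n = data.n
    edges = work.edges
    n_e = len(edges)

    # per-edge squared distances, updated incrementally as vertices move
    D = np.empty((n_e, n))
    for i, (j, k) in enumerate(edges):
        D[i] = segment_sq_distances(X, emb[j], emb[k])[1]

    incident = [work.incident_edge_indices(v) for v in range(work.n_vertices)]
    sq_edge_lengths = np.array([float((emb[j] - emb[k]) @ (emb[j] - emb[k]))
                                for j, k in edges])
    lam1 = float(cfg.lambda1)
    size_pen = lam1 * work.n_vertices ** cfg.alpha

    def total() -> float:
        return (float(np.min(D, axis=0).sum()) + size_pen
                + cfg.lambda2 * float(sq_edge_lengths.sum()))

    trace = [total()]
    prev = trace[0]
    for _sweep in range(cfg.max_sweeps):
        for v in range(work.n_vertices):
            inc = incident[v]
            if n_e > len(inc):
                mask = np.ones(n_e, dtype=bool)
                mask[inc] = False
                other_sq = np.min(D[mask], axis=0)
            else:
                other_sq = np.full(n, np.inf)
            shell = EmbeddingTree(emb, edges)
            problem = _VertexProblem(shell, v, data, cfg, other_sq=other_sq)
            y0 = emb[v]
            y_star, s_star = _line_search_minimize(y0, problem, cfg)
            if s_star <= problem(y0):
                emb[v] = y_star
                for i in inc:
                    j, k = edges[i]
                    D[i] = segment_sq_distances(X, emb[j], emb[k])[1]
                    sq_edge_lengths[i] = float((emb[j] - emb[k]) @ (emb[j] - emb[k]))
            if return_trace:
                trace.append(total())
        cur = total()
        if prev - cur <= cfg.tol * (1.0 + abs(cur)):
            break
        prev = cur

    result = EmbeddingTree(emb, edges)
    if return_trace:
        return result, trace
    return result
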