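"""The stochastic tree search (STS) loop.

The search explores tree space by size.  It starts from a pool of
one-edge trees whose endpoints are drawn from a normal approximation of
the data, refines every candidate with the vertex optimizer, and then
repeatedly grows trees by one vertex: either a new leaf attached to a
uniformly chosen vertex and placed on a residual-weighted data row, or a
midpoint splitting a uniformly chosen edge.  Grown candidates are refined
and admitted to the next-size pool under a diversity/quality rule: once
the pool is full, a candidate replaces its most-similar pool member only
when it is sufficiently different from everything in the pool
(similarity score above the cutoff ``a``) and its penalized objective S2
beats the pool's best.  Growth stops as soon as the best S2 at size k+1
exceeds the best at size k — the BIC-style size penalty makes this the
model-selection rule — and the best tree at the last improving size is
returned.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .objective import score_S2
from .optimize import optimize_embedding
from .projection import project_points
from .similarity import tree_similarity
from .tree import Dataset, EmbeddingTree, STSConfig, validate_tree

__all__ = [
    "TreePool",
    "SearchTrace",
    "init_pool",
    "grow_add_leaf",
    "grow_split_edge",
    "try_admit",
    "run_sts",
]


@dataclasses.dataclass
class TreePool:
    """Fixed-capacity collection of same-size candidate trees with their
    S2 scores."""

    capacity: int
    trees: list[EmbeddingTree] = dataclasses.field(default_factory=list)
    scores: list[float] = dataclasses.field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trees)

    @property
    def size(self) -> int | None:
        """Common vertex count of member trees (None when empty)."""
        return self.trees[0].n_vertices if self.trees else None

    def best(self) -> tuple[EmbeddingTree, float]:
        i = int(np.argmin(self.scores))
        return self.trees[i], self.scores[i]

    def sorted_scores(self) -> list[float]:
        return sorted(self.scores)


@dataclasses.dataclass
class SearchTrace:
    """Reproducibility log of one search run."""

    seed: int
    best_s2_per_size: dict[int, float] = dataclasses.field(default_factory=dict)
    accepted: int = 0
    rejected: int = 0
    final_size: int = 0

    def to_json(self, path=None) -> str:
        d = dataclasses.asdict(self)
        d["best_s2_per_size"] = {str(k): v for k, v in d["best_s2_per_size"].items()}
        text = json.dumps(d)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def init_pool(data: Dataset, cfg: STSConfig,
              rng: np.random.Generator | None = None) -> TreePool:
    """Pool of ``L1`` refined one-edge trees.

    Both endpoints of every initial tree are i.i.d. draws from
    ``MVN(mean(X), diag(var(X)))``, then the vertex optimizer fits them to
    the data.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    cfg = cfg.resolve(data)
    mu = data.X.mean(axis=0)
    sd = data.X.std(axis=0, ddof=1)
    if not np.any(sd > 0):
        raise ValueError("degenerate data: zero variance in every column")
    pool = TreePool(capacity=cfg.pool_size_L1)
    for _ in range(cfg.pool_size_L1):
        emb = mu + sd * rng.standard_normal((2, data.p))
        tree = optimize_embedding(EmbeddingTree(emb, ((0, 1),)), data, cfg)
        pool = try_admit(pool, tree, data, cfg)
    return pool


def grow_add_leaf(tree: EmbeddingTree, data: Dataset, cfg: STSConfig,
                  rng: np.random.Generator) -> EmbeddingTree:
    """Attach a new leaf to a uniformly chosen vertex; place it on a data
    row sampled with residual-driven weights ``w_i = exp(lambda3 * r_i*)``
    where ``r_i*`` are the squared residuals standardized by their max.

    Larger ``lambda3`` concentrates placement in poorly fitted regions;
    ``lambda3 = 0`` samples uniformly.
    """
    k = tree.n_vertices
    attach = int(rng.integers(k))
    r = project_points(data.X, tree).sq_residual
    rmax = float(r.max())
    r_star = r / rmax if rmax > 0 else np.zeros_like(r)
    w = np.exp(cfg.lambda3 * r_star)
    probs = w / w.sum()
    row = int(rng.choice(data.n, p=probs))
    emb = np.vstack([tree.embedding, data.X[row]])
    edges = tree.edges + ((attach, k),)
    return EmbeddingTree(emb, edges)


def grow_split_edge(tree: EmbeddingTree,
                    rng: np.random.Generator) -> EmbeddingTree:
    """Split a uniformly chosen edge at its midpoint with a new vertex."""
    k = tree.n_vertices
    idx = int(rng.integers(len(tree.edges)))
    j, g = tree.edges[idx]
    y_new = 0.5 * (tree.embedding[j] + tree.embedding[g])
    emb = np.vstack([tree.embedding, y_new])
    edges = tuple(e for i, e in enumerate(tree.edges) if i != idx)
    edges += ((j, k), (g, k))
    return EmbeddingTree(emb, edges)


def try_admit(pool: TreePool, candidate: EmbeddingTree, data: Dataset,
              cfg: STSConfig) -> TreePool:
    """Admit ``candidate`` to ``pool`` under the diversity/quality rule.

    A pool below capacity admits unconditionally.  A full pool replaces
    the member most similar to the candidate only when
    S1(candidate) = min_member similarity(candidate, member) exceeds the
    cutoff ``a`` *and* the candidate's S2 beats the pool's best S2 (or the
    pool's worst when ``cfg.admit_vs_worst`` is set).
    """
    if not validate_tree(candidate):
        raise ValueError("candidate tree is invalid")
    if pool.size is not None and candidate.n_vertices != pool.size:
        raise ValueError("candidate size differs from pool size")
    cfg = cfg.resolve(data)
    s2 = score_S2(data, candidate, cfg)
    if len(pool) < pool.capacity:
        pool.trees.append(candidate)
        pool.scores.append(s2)
        return pool
    sims = [tree_similarity(candidate, t) for t in pool.trees]
    s1 = min(sims)
    threshold = max(pool.scores) if cfg.admit_vs_worst else min(pool.scores)
    if s1 > cfg.similarity_cutoff_a and s2 < threshold:
        i_min = int(np.argmin(sims))
        pool.trees[i_min] = candidate
        pool.scores[i_min] = s2
    return pool


def run_sts(data: Dataset, cfg: STSConfig) -> tuple[EmbeddingTree, SearchTrace]:
    """Run the full stochastic tree search; returns the optimal tree and
    a reproducibility trace.

    All randomness flows from a single generator seeded with
    ``cfg.seed``, so runs are bit-identical under the same seed.
    """
    rng = np.random.default_rng(cfg.seed)
    cfg = cfg.resolve(data)
    trace = SearchTrace(seed=cfg.seed)

    pool = init_pool(data, cfg, rng)
    best_tree, best_s2 = pool.best()
    trace.best_s2_per_size[2] = best_s2

    size = 2
    while size + 1 <= cfg.max_tree_size:
        new_pool = TreePool(capacity=cfg.pool_size_L1)
        for _round in range(cfg.grow_repeats_L2):
            parent = pool.trees[int(rng.integers(len(pool)))]
            if rng.random() < cfg.leaf_move_prob:
                candidate = grow_add_leaf(parent, data, cfg, rng)
            else:
                candidate = grow_split_edge(parent, rng)
            candidate = optimize_embedding(candidate, data, cfg)
            before = (len(new_pool), tuple(new_pool.scores))
            new_pool = try_admit(new_pool, candidate, data, cfg)
            if (len(new_pool), tuple(new_pool.scores)) != before:
                trace.accepted += 1
            else:
                trace.rejected += 1
        if len(new_pool) == 0:
            break
        cand_tree, cand_s2 = new_pool.best()
        trace.best_s2_per_size[size + 1] = cand_s2
        if cand_s2 > best_s2:
            break  # larger trees no longer pay for their complexity
        best_tree, best_s2 = cand_tree, cand_s2
        pool = new_pool
        size += 1

    trace.final_size = best_tree.n_vertices
    return best_tree, trace
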