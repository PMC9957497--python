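"""Penalized least-squares objective for embedding-tree fitting.

Assuming cells scatter around their tree projections with isotropic
Gaussian noise, the negative log-likelihood is proportional to the sum of
squared projection residuals

    f(T) = sum_i ||x_i - phi_T(x_i)||^2 ,

and the fitted tree minimizes the penalized form ``f(T) + p(T)`` with

    p(T) = lambda1 |V|^alpha + lambda2 * sum_{(j,k) in E} ||y_j - y_k||^2 .

The size term is calibrated against BIC: with ``alpha = 1`` and
``lambda1 = sigma2_hat * p * log(n)`` each extra vertex costs as much as
its ~p free coordinates would under BIC.  The small length term
(``lambda2 = 0.01`` by default) discourages needlessly long edges.

The total is also the pool-ranking score S2 used by the stochastic search
(lower is better).
"""

from __future__ import annotations

import dataclasses
import json
import math

import numpy as np

from .projection import project_points
from .tree import Dataset, EmbeddingTree, STSConfig, tree_edge_lengths

__all__ = [
    "ObjectiveBreakdown",
    "loss",
    "penalty",
    "auto_lambda1",
    "score_S2",
    "objective_breakdown",
]


@dataclasses.dataclass(frozen=True)
class ObjectiveBreakdown:
    loss: float
    size_penalty: float
    length_penalty: float
    total: float

    @property
    def S2(self) -> float:
        return self.total

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self) | {"S2": self.S2})


def loss(data: Dataset, tree: EmbeddingTree) -> float:
    """Sum of squared projection residuals f(T)."""
    return float(project_points(data.X, tree).sq_residual.sum())


def _resolved_lambda1(cfg: STSConfig, data: Dataset | None) -> float:
    if cfg.lambda1 == "auto":
        if data is None:
            raise ValueError("lambda1='auto' requires a dataset to resolve")
        return auto_lambda1(data)
    return float(cfg.lambda1)


def penalty(tree: EmbeddingTree, cfg: STSConfig,
            data: Dataset | None = None) -> float:
    """Penalty p(T) = lambda1 |V|^alpha + lambda2 * sum of squared edge lengths."""
    lam1 = _resolved_lambda1(cfg, data)
    sq_lengths = sum(v ** 2 for v in tree_edge_lengths(tree).values())
    return lam1 * tree.n_vertices ** cfg.alpha + cfg.lambda2 * sq_lengths


def auto_lambda1(data: Dataset) -> float:
    """BIC-derived size-penalty weight: sigma2_hat * p * log(n)."""
    if data.n < 2:
        raise ValueError("need at least 2 cells to set lambda1")
    return float(data.sigma2_hat) * data.p * math.log(data.n)


def objective_breakdown(data: Dataset, tree: EmbeddingTree,
                        cfg: STSConfig) -> ObjectiveBreakdown:
    lam1 = _resolved_lambda1(cfg, data)
    f = loss(data, tree)
    size_pen = lam1 * tree.n_vertices ** cfg.alpha
    sq_lengths = sum(v ** 2 for v in tree_edge_lengths(tree).values())
    length_pen = cfg.lambda2 * sq_lengths
    return ObjectiveBreakdown(f, size_pen, length_pen, f + size_pen + length_pen)


def score_S2(data: Dataset, tree: EmbeddingTree, cfg: STSConfig) -> float:
    """Pool-ranking score: the full penalized objective (lower is better)."""
    return objective_breakdown(data, tree, cfg).total
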