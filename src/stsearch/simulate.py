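"""Synthetic trajectory data and the simulation benchmark.

The generator emulates the standard trajectory-recovery study design:
a random k-vertex embedding tree in p dimensions (vertex coordinates
i.i.d. N(0, I_p), topology by sequential uniform attachment), n cells
placed on the tree (an edge chosen with probability proportional to its
length, a position uniform along it), and isotropic noise added to each
coordinate — either standard normal or Student t with 3 degrees of
freedom, scaled by the noise level sigma.  The t3 option produces heavy
tails and occasional extreme outliers.

Two evaluation metrics accompany the generator: the Kendall rank
correlation between estimated and true pseudotimes (cell-ordering
accuracy), and the residual standard error — the root mean squared
distance between fitted-tree projections and the true generating
projections (trajectory-estimation accuracy).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .projection import project_points
from .pseudotime import compute_pseudotime, kendall_correlation
from .search import run_sts
from .tree import Dataset, EmbeddingTree, STSConfig, tree_edge_lengths

__all__ = [
    "SimulatedDataset",
    "simulate_tree",
    "simulate_cells",
    "residual_standard_error",
    "evaluate_fit",
    "benchmark_lambda1",
    "run_benchmark",
    "summarize_benchmark",
]


@dataclasses.dataclass
class SimulatedDataset:
    """Noisy observations together with the generating ground truth."""

    X: np.ndarray                 # (n, p) noisy observations
    true_tree: EmbeddingTree
    true_projection: np.ndarray   # (n, p) points on true_tree
    true_pseudotime: np.ndarray   # (n,) geodesic distance from root leaf
    root_vertex: int
    noise_kind: str               # "normal" | "t3"
    sigma: float
    curvature_c: float = 0.0      # only straight edges (c = 0) supported
    seed: int | None = None

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def dataset(self) -> Dataset:
        return Dataset.from_array(self.X)


def simulate_tree(k: int, p: int, rng: np.random.Generator) -> EmbeddingTree:
    """Random k-vertex tree in R^p: coordinates i.i.d. N(0, I_p),
    topology by sequential uniform attachment."""
    if k < 2 or p < 1:
        raise ValueError("need k >= 2 vertices and p >= 1 dimensions")
    emb = rng.standard_normal((k, p))
    edges = tuple((int(rng.integers(v)), v) for v in range(1, k))
    return EmbeddingTree(emb, edges)


def simulate_cells(tree: EmbeddingTree, n: int, sigma: float,
                   noise_kind: str, rng: np.random.Generator,
                   seed: int | None = None) -> SimulatedDataset:
    """Place n cells on ``tree`` and add scaled noise.

    Each cell's true position picks an edge length-proportionally and a
    uniform position along it; the observation adds ``sigma`` times an
    i.i.d. per-coordinate draw from N(0,1) or t3 (the t3 draw is used
    raw, so its variance of 3 is part of the noise model, not rescaled
    away).  True pseudotime is the geodesic distance from the root — the
    leaf with the smallest vertex id.
    """
    if n < 2 or sigma < 0:
        raise ValueError("need n >= 2 cells and sigma >= 0")
    if noise_kind not in ("normal", "t3"):
        raise ValueError("noise_kind must be 'normal' or 't3'")
    p = tree.dimension
    lengths = tree_edge_lengths(tree)
    edge_list = list(lengths)
    weights = np.array([lengths[e] for e in edge_list])
    if weights.sum() <= 0:
        raise ValueError("tree has zero total length")
    probs = weights / weights.sum()
    edge_idx = rng.choice(len(edge_list), size=n, p=probs)
    ls = rng.uniform(size=n)
    y = tree.embedding
    ej = np.array([edge_list[i][0] for i in edge_idx])
    ek = np.array([edge_list[i][1] for i in edge_idx])
    proj = y[ej] + ls[:, None] * (y[ek] - y[ej])
    if noise_kind == "normal":
        eps = rng.standard_normal((n, p))
    else:
        eps = rng.standard_t(3, size=(n, p))
    X = proj + sigma * eps

    root = min(tree.leaves())
    # true pseudotime: geodesic from the root vertex to each true position
    res = compute_pseudotime(Dataset(proj, [f"cell{i}" for i in range(n)],
                                     sigma2_hat=1.0), tree, root)
    true_pt = res.values_for([f"cell{i}" for i in range(n)])
    return SimulatedDataset(X, tree, proj, true_pt, root, noise_kind,
                            float(sigma), 0.0, seed)


def residual_standard_error(fitted: EmbeddingTree,
                            sim: SimulatedDataset) -> float:
    """Root mean squared distance between fitted-tree projections of the
    observations and the true generating projections."""
    proj = project_points(sim.X, fitted)
    diff = proj.points - sim.true_projection
    return float(np.sqrt(np.mean(np.einsum("ij,ij->i", diff, diff))))


def evaluate_fit(fitted: EmbeddingTree, sim: SimulatedDataset) -> dict:
    """Kendall tau (ordering accuracy) and residual standard error
    (trajectory accuracy) of a fitted tree against the ground truth.

    The estimated origin is the point of the fitted tree nearest to the
    true root vertex's location, mirroring how a known starting state
    anchors pseudotime on real data.
    """
    from .projection import project_to_tree

    ids = [f"cell{i}" for i in range(sim.n)]
    data = Dataset(sim.X, ids, sigma2_hat=1.0)
    root_coord = sim.true_tree.embedding[sim.root_vertex]
    anchor = project_to_tree(root_coord, fitted)
    res = compute_pseudotime(data, fitted, (anchor.edge, anchor.l))
    est = res.values_for(ids)
    tau = kendall_correlation(est, sim.true_pseudotime)
    return {
        "kendall": tau,
        "rse": residual_standard_error(fitted, sim),
        "fitted_size": fitted.n_vertices,
    }


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2 ** 31))


#: nominal lower bound on the noise scale used when calibrating the size
#: penalty for (near-)noiseless data, where the plug-in BIC weight would
#: otherwise degenerate to zero
SIGMA_FLOOR = 0.05


#: per-vertex degrees of freedom beyond the raw coordinate count: each
#: vertex contributes its p coordinates and roughly one edge's worth of
#: assignment flexibility; the doubled charge prevents the stochastic
#: search from padding trees with noise-absorbing vertices
DOF_FACTOR = 2.0


def benchmark_lambda1(sigma: float, noise_kind: str, p: int, n: int) -> float:
    """BIC-style size-penalty weight for simulated data with *known* noise.

    The generative model assumes a known noise variance; in simulation it
    is sigma^2 for normal noise and 3 sigma^2 for t3 (the variance of a
    t3 draw).  A floor keeps the penalty positive for noiseless data, and
    the complexity charge per vertex is DOF_FACTOR * p * log n.
    """
    var = sigma ** 2 * (3.0 if noise_kind == "t3" else 1.0)
    return max(var, SIGMA_FLOOR ** 2) * DOF_FACTOR * p * math.log(n)


def run_benchmark(grid, reps: int, k: int = 5, p: int = 4, n: int = 200,
                  cfg: STSConfig | None = None, seed: int = 0,
                  paired: bool = False) -> pd.DataFrame:
    """Simulate -> fit -> evaluate over a grid of noise conditions.

    Parameters
    ----------
    grid
        Iterable of ``(sigma, noise_kind)`` pairs.
    reps
        Independent replicates per grid cell.
    paired
        When True, replicate r shares one generating tree, one set of
        cell positions and one set of unit noise draws across all grid
        cells (only the noise scale/distribution differs).  Common random
        numbers sharpen comparisons across noise levels.

    Returns a tidy frame with columns sigma, noise_kind, rep, kendall,
    rse, fitted_size, seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if cfg is None:
        cfg = STSConfig()
    grid = list(grid)
    root_ss = np.random.SeedSequence(seed)
    rows = []
    if paired:
        rep_seeds = root_ss.spawn(reps)
        for rep, ss in enumerate(rep_seeds):
            sim_ss, fit_ss = ss.spawn(2)
            gen = np.random.default_rng(sim_ss)
            tree = simulate_tree(k, p, gen)
            base = simulate_cells(tree, n, 1.0, "normal", gen)
            unit_normal = base.X - base.true_projection  # unit-scale draws
            gen_t = np.random.default_rng(sim_ss.spawn(1)[0])
            unit_t3 = gen_t.standard_t(3, size=unit_normal.shape)
            for sigma, noise_kind in grid:
                eps = unit_normal if noise_kind == "normal" else unit_t3
                sim = dataclasses.replace(
                    base, X=base.true_projection + sigma * eps,
                    sigma=float(sigma), noise_kind=noise_kind)
                rows.append(_one_rep(sim, cfg, _child_seed(fit_ss), rep))
    else:
        cell_seeds = root_ss.spawn(len(grid))
        for (sigma, noise_kind), cell_ss in zip(grid, cell_seeds):
            for rep, ss in enumerate(cell_ss.spawn(reps)):
                sim_ss, fit_ss = ss.spawn(2)
                gen = np.random.default_rng(sim_ss)
                tree = simulate_tree(k, p, gen)
                sim = simulate_cells(tree, n, sigma, noise_kind, gen)
                rows.append(_one_rep(sim, cfg, _child_seed(fit_ss), rep))
    return pd.DataFrame(rows)


def _one_rep(sim: SimulatedDataset, cfg: STSConfig, fit_seed: int,
             rep: int) -> dict:
    run_cfg = dataclasses.replace(cfg, seed=fit_seed)
    if run_cfg.lambda1 == "auto":
        # the simulation's noise variance is known by design
        run_cfg = dataclasses.replace(
            run_cfg, lambda1=benchmark_lambda1(sim.sigma, sim.noise_kind,
                                               sim.X.shape[1], sim.n))
    data = Dataset.from_array(sim.X)
    try:
        fitted, _ = run_sts(data, run_cfg)
        metrics = evaluate_fit(fitted, sim)
        error = ""
    except Exception as exc:  # record, never abort the whole benchmark
        metrics = {"kendall": np.nan, "rse": np.nan, "fitted_size": 0}
        error = repr(exc)
    return {
        "sigma": sim.sigma,
        "noise_kind": sim.noise_kind,
        "rep": rep,
        "seed": fit_seed,
        **metrics,
        "error": error,
    }


def summarize_benchmark(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of both metrics per (sigma, noise_kind) condition."""
    return (results.groupby(["sigma", "noise_kind"])
            .agg(kendall_mean=("kendall", "mean"),
                 kendall_sd=("kendall", "std"),
                 rse_mean=("rse", "mean"),
                 rse_sd=("rse", "std"),
                 n_reps=("rep", "count"))
            .reset_index())
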