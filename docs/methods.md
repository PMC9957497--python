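# Methods

## Model

`stsearch` reconstructs a single-cell trajectory as an *embedding tree*
`T = (V, E, y)`: a connected acyclic graph whose vertices carry coordinates
`y_j` in the dimension-reduced expression space `R^p`, with edges treated as
straight segments.  Cells are modeled as noisy observations of points on the
tree,

    x_i | T  ~  N(phi_T(x_i), sigma^2 I_p),

where `phi_T(x)` is the nearest point of the tree to `x`.  Up to constants
the negative log-likelihood is the sum of squared projection residuals, and
the fitted tree minimizes the penalized objective

    f(T) + p(T),
    f(T) = sum_i || x_i - phi_T(x_i) ||^2,
    p(T) = lambda1 |V|^alpha + lambda2 sum_{(j,k) in E} || y_j - y_k ||^2.

With `alpha = 1` and `lambda1 = sigma^2 p log n` the size term reproduces a
BIC complexity charge (each vertex contributes ~p free coordinates); the
small length term (`lambda2 = 0.01`) discourages gratuitously long edges.
The same quantity, written `S2(T)`, ranks candidate trees during the search
and drives the stopping rule.

Projections have a closed form per edge: the segment parameter is
`l = clip(<x - y_j, y_k - y_j> / ||y_k - y_j||^2, 0, 1)` and the tree
projection is the best edge projection.  Zero-length edges (possible
transiently while optimizing) project to their common endpoint, which keeps
the distance continuous as an edge collapses.

## Vertex optimization

For a fixed topology, each vertex `v` in turn minimizes

    S(y) = f(T with v at y) + lambda2 sum_{k in N(v)} || y - y_k ||^2

by gradient descent with a backtracking line search: forward-difference
gradients (step `1e-6`), step size starting at 1 and shrinking by the factor
0.8 until the sufficient-decrease test with constant 0.5 holds.  Because `S`
is piecewise smooth (the cell-to-edge assignment changes with `y`), the
implementation additionally accepts a step only if `S` does not increase, so
every vertex update — and hence the whole sweep — is monotone
non-increasing in the total objective.  Sweeps visit vertices in ascending
id order and stop when the relative improvement of the total objective
falls below `tol` (default `1e-5`) or after 100 sweeps; each per-vertex line
search is capped at 50 gradient steps and 60 shrinks.  Moving one vertex
only changes its incident segments, so each cell's residual is the minimum
of a cached distance-to-the-rest-of-the-tree and its distance to the
incident segments; this inner evaluation is JIT-compiled (numba) with a
semantically identical numpy fallback.

## Stochastic search

The tree space is explored by size `k = 2, 3, ...` with a pool of `L1 = 10`
candidate trees per size:

1. **Init.**  `L1` one-edge trees with endpoints drawn from
   `MVN(mean(X), diag(var(X)))`, each refined by the vertex optimizer.
2. **Growth.**  For `L2 = 80` rounds per size, a uniformly chosen pool
   member is grown by one vertex: with probability 1/2 a new leaf is
   attached to a uniformly chosen vertex and placed on a data row sampled
   with weights `exp(lambda3 r_i*)` (`r_i*` = squared residuals scaled by
   their maximum, `lambda3 = 1`); otherwise a uniformly chosen edge is split
   at its midpoint.  The grown tree is refined and offered to the
   next-size pool.
3. **Admission.**  A pool below capacity admits unconditionally.  A full
   pool replaces the member nearest to the candidate only when the
   candidate is sufficiently different from every member (similarity score
   above the cutoff `a`, default 2% of the data diameter) and its `S2`
   beats the pool's best.  A variant comparing against the pool's worst
   member is available (`admit_vs_worst`).
4. **Stopping.**  Growth stops when the best `S2` at size `k+1` exceeds the
   best at size `k` (or at a safety cap of 30 vertices); the best tree at
   the last improving size is returned.

The tree similarity score is a geometric discrepancy: the sum over vertices
of one tree of the distance to the nearest vertex of the other, plus the
sum over edges of the endpoint discrepancy `sqrt(d1^2 + d2^2)` to the
nearest edge.  Both parts are nearest-match sums, so identical trees score
exactly zero and the admission gate "score > a" keeps the pool diverse.
The score is directional; admission always evaluates
`similarity(candidate, pool_member)`.

All randomness flows from one seeded generator, so runs are bit-identical
under the same seed.

## Pseudotime

Each edge is weighted by the Euclidean distance of its endpoints; a cell's
pseudotime is the shortest-path length along the tree from a chosen origin
to the cell's projection.  The origin can be a vertex, a cell (its
projection becomes the origin), or an explicit point on the tree.  Cell
ordering sorts by pseudotime with ties broken by cell id.  The origin
encodes prior biological knowledge (a known starting state); the method
itself does not infer it.  Kendall's tau-b (tie-corrected) compares two
pseudotime assignments.

## Synthetic data and benchmark

The generator emulates the standard trajectory-recovery design: a k-vertex
tree with coordinates i.i.d. `N(0, I_p)` and topology by sequential uniform
attachment; `n` cells placed on the tree, each picking an edge with
probability proportional to its length and a uniform position along it
(the least-informative arc-length choice); observations add `sigma` times
i.i.d. per-coordinate noise, standard normal or Student t3 (the raw t3 draw
is scaled by `sigma`, so its variance `3 sigma^2` is part of the noise
model).  True pseudotime is measured from the smallest-id leaf.

Two metrics score a fit against the generating truth:

- **Kendall tau-b** between estimated and true pseudotime.  The estimated
  origin is anchored at the point of the fitted tree nearest to the true
  root's location, mirroring how a known starting state anchors real
  analyses.  Anchoring at the projection of a single noisy origin *cell*
  proved fragile (one outlying draw can flip the whole ordering) and is not
  used for evaluation.
- **Residual standard error**: root mean squared distance between
  fitted-tree projections and the true generating projections.

Benchmark defaults: `k = 5`, `p = 4`, `n = 200`, `sigma = 0.10`, 50
replicates.  Because the generative model treats the noise variance as
known, the benchmark sets `lambda1 = Var(noise) * p * log n` directly
(`Var = sigma^2` for normal, `3 sigma^2` for t3), with a floor at a nominal
noise scale of 0.05 so that noiseless data keep a positive size penalty —
without it, midpoint splits (which always reduce the squared-length
penalty) would grow trees to the size cap.

**Why p = 4.**  With vertex coordinates drawn from `N(0, I_p)`, distinct
branches of a random tree frequently cross or overlap in two dimensions.
In that regime trajectory recovery is ill-posed for *any* method: we
verified that even the generating tree orders cells at only tau ≈ 0.83 on
average, and that the penalized objective's global optimum at matched size
is often a "mis-wired" tree whose long edges cover the point cloud with a
*lower* objective than the refined truth while scrambling geodesic order.
In four dimensions random branches are almost surely separated, the
objective's optimum coincides with the true wiring, and the method operates
in the well-posed regime its design assumes.  The benchmark therefore
simulates in `p = 4`.

**What the generator does not emulate.**  Real single-cell data have
non-Gaussian, gene-dependent noise, uneven cell density along the process,
batch effects, and a dimension-reduction step whose distortions are absent
here.  Passing the benchmark demonstrates correct recovery under the
generative model, not performance on any particular real dataset.

## Numerical choices

- Pool ties and projection ties resolve to the smallest canonical edge /
  lowest index, making every code path deterministic.
- `tol = 1e-5` (relative change of the penalized objective) balances
  optimizer depth against runtime; descent is guaranteed regardless.
- Degenerate inputs fail fast: non-finite coordinates, fewer than two
  cells, zero-variance data for pool initialization.
- The sufficient-decrease test uses the printed positive right-hand side
  `c tau ||grad||^2`; the extra non-ascent clause makes it a descent
  method even at kinks of `S`.
- Sample variance estimates use `ddof = 1` throughout.

## Limitations

- Edges are straight segments; smoothly curved trajectories are represented
  only piecewise.
- The search is stochastic: different seeds can return different tree
  sizes near the model-selection boundary.
- The origin for pseudotime must be supplied by the user on real data.
- The data-driven default `lambda1` (pooled per-dimension variance of the
  reduced data) deliberately over-penalizes tree size when the signal
  variance dominates the noise; supply a noise-calibrated `lambda1` when an
  estimate of the measurement noise is available.
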