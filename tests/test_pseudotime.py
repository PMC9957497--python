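"""Geodesics on trees and pseudotime against an augmented-graph Dijkstra
oracle; Kendall tau against brute-force pair counting."""

import itertools

import networkx as nx
import numpy as np
import pytest

from stsearch import (Dataset, EmbeddingTree, compute_pseudotime,
                      kendall_correlation, tree_edge_lengths, tree_geodesic)
from stsearch.projection import project_points, project_to_tree

from conftest import random_tree


def dijkstra_oracle(tree, a, b):
    """Distance between two on-tree points via a graph augmented with the
    points as temporary vertices."""
    g = nx.Graph()
    lengths = tree_edge_lengths(tree)
    for (j, k), w in lengths.items():
        g.add_edge(j, k, weight=w)
    for name, ((j, k), l) in (("A", a), ("B", b)):
        w = lengths[(j, k)]
        g.add_edge(name, j, weight=l * w)
        g.add_edge(name, k, weight=(1 - l) * w)
    # same-edge pairs also have the direct along-edge connection
    if a[0] == b[0]:
        g.add_edge("A", "B", weight=abs(a[1] - b[1]) * lengths[a[0]])
    return nx.dijkstra_path_length(g, "A", "B", weight="weight")


class TestTreeGeodesic:
    def test_hand_computed_path(self):
        t = EmbeddingTree(np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]),
                          ((0, 1), (1, 2)))
        d = tree_geodesic(t, ((0, 1), 0.0), ((1, 2), 0.5))
        assert d == pytest.approx(1.5)

    def test_same_point_zero(self, star_tree):
        assert tree_geodesic(star_tree, ((0, 1), 0.3), ((0, 1), 0.3)) == 0.0

    def test_point_off_tree_raises(self, star_tree):
        with pytest.raises(ValueError):
            tree_geodesic(star_tree, ((1, 2), 0.5), ((0, 1), 0.0))

    def test_matches_dijkstra_oracle(self, rng):
        for _ in range(40):
            t = random_tree(rng, 6, p=2)
            if any(v < 1e-9 for v in tree_edge_lengths(t).values()):
                continue
            e1, e2 = rng.integers(len(t.edges), size=2)
            a = (t.edges[e1], float(rng.uniform()))
            b = (t.edges[e2], float(rng.uniform()))
            assert tree_geodesic(t, a, b) == pytest.approx(
                dijkstra_oracle(t, a, b), abs=1e-9)

    def test_triangle_property_with_equality_on_path(self, rng):
        t = random_tree(rng, 5, p=2)
        pts = []
        for _ in range(3):
            e = t.edges[int(rng.integers(len(t.edges)))]
            pts.append((e, float(rng.uniform())))
        a, b, c = pts
        dab = tree_geodesic(t, a, b)
        dbc = tree_geodesic(t, b, c)
        dac = tree_geodesic(t, a, c)
        assert dac <= dab + dbc + 1e-9


class TestComputePseudotime:
    def test_cells_on_origin_vertex_all_zero(self, path_tree):
        X = np.zeros((5, 2))
        d = Dataset(X, list("abcde"), sigma2_hat=1.0)
        res = compute_pseudotime(d, path_tree, 0)
        assert all(v == pytest.approx(0.0) for v in res.pseudotime.values())

    def test_evenly_spaced_cells_on_edge(self):
        t = EmbeddingTree(np.array([[0.0, 0.0], [4.0, 0.0]]), ((0, 1),))
        xs = np.array([[1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
        d = Dataset(xs, ["a", "b", "c"], sigma2_hat=1.0)
        res = compute_pseudotime(d, t, 0)
        assert [res.pseudotime[c] for c in "abc"] == pytest.approx([1.0, 2.0, 3.0])
        assert res.order == ["a", "b", "c"]

    def test_matches_dijkstra_oracle_on_random_instances(self, rng):
        for _ in range(10):
            t = random_tree(rng, 5, p=2)
            X = rng.standard_normal((20, 2))
            d = Dataset.from_array(X)
            origin = int(rng.integers(t.n_vertices))
            res = compute_pseudotime(d, t, origin)
            proj = project_points(X, t)
            inc = t.incident_edge_indices(origin)
            oe = t.edges[inc[0]]
            opt = (oe, 0.0 if oe[0] == origin else 1.0)
            for i, cell in enumerate(d.cell_ids):
                cell_pt = (t.edges[int(proj.edge_index[i])], float(proj.l[i]))
                assert res.pseudotime[cell] == pytest.approx(
                    dijkstra_oracle(t, opt, cell_pt), abs=1e-9)

    def test_origin_as_cell_projection(self, rng):
        t = random_tree(rng, 4, p=2)
        X = rng.standard_normal((10, 2))
        d = Dataset.from_array(X)
        res = compute_pseudotime(d, t, d.cell_ids[3])
        assert res.pseudotime[d.cell_ids[3]] == pytest.approx(0.0, abs=1e-12)

    def test_farthest_leaf_origin_reverses_path_order(self):
        t = EmbeddingTree(np.array([[0.0, 0.0], [5.0, 0.0]]), ((0, 1),))
        X = np.column_stack([np.linspace(0.5, 4.5, 9), np.zeros(9)])
        d = Dataset.from_array(X)
        fwd = compute_pseudotime(d, t, 0)
        bwd = compute_pseudotime(d, t, 1)
        assert fwd.order == bwd.order[::-1]

    def test_rigid_motion_invariance(self, rng):
        t = random_tree(rng, 5, p=2)
        X = rng.standard_normal((15, 2))
        theta = 0.6
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        shift = np.array([2.0, -7.0])
        t2 = EmbeddingTree(t.embedding @ R.T + shift, t.edges)
        a = compute_pseudotime(Dataset.from_array(X), t, 0)
        b = compute_pseudotime(Dataset.from_array(X @ R.T + shift), t2, 0)
        for c in a.pseudotime:
            assert b.pseudotime[c] == pytest.approx(a.pseudotime[c], abs=1e-9)

    def test_bad_origin_raises(self, path_tree):
        d = Dataset.from_array(np.random.default_rng(0).standard_normal((5, 2)))
        with pytest.raises(ValueError):
            compute_pseudotime(d, path_tree, 99)
        with pytest.raises(ValueError):
            compute_pseudotime(d, path_tree, "no-such-cell")


class TestSuggestOrigin:
    def test_picks_leaf_near_extreme_cell(self):
        from stsearch import suggest_origin

        t = EmbeddingTree(np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]),
                          ((0, 1), (1, 2)))
        X = np.array([[-0.1, 0.0], [0.9, 0.1], [2.1, 0.0]])
        d = Dataset.from_array(X)
        assert suggest_origin(d, t, feature=0) == 0
        with pytest.raises(ValueError):
            suggest_origin(d, t, feature=5)


def brute_force_tau_b(x, y):
    """O(n^2) concordant/discordant pair counting with tie correction."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        a = np.sign(x[i] - x[j])
        b = np.sign(y[i] - y[j])
        if a == 0 and b == 0:
            continue
        if a == 0:
            tx += 1
        elif b == 0:
            ty += 1
        elif a == b:
            conc += 1
        else:
            disc += 1
    denom = np.sqrt((conc + disc + tx) * (conc + disc + ty))
    return (conc - disc) / denom


class TestKendallCorrelation:
    def test_identical_orderings(self):
        assert kendall_correlation([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)

    def test_reversed_orderings(self):
        assert kendall_correlation([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            kendall_correlation([1.0, 1.0, 1.0], [1, 2, 3])

    def test_matches_brute_force_with_ties(self, rng):
        for _ in range(10):
            x = rng.integers(0, 5, size=12).astype(float)
            y = rng.integers(0, 5, size=12).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            assert kendall_correlation(x, y) == pytest.approx(
                brute_force_tau_b(x, y), abs=1e-12)
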