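"""Stochastic search: growth moves, pool admission, determinism,
end-to-end recovery on easy instances."""

import dataclasses

import numpy as np
import pytest

from stsearch import (Dataset, EmbeddingTree, STSConfig, grow_add_leaf,
                      grow_split_edge, init_pool, loss, run_sts, score_S2,
                      try_admit, validate_tree)
from stsearch.search import TreePool

from conftest import random_tree


@pytest.fixture
def segment_data(rng):
    """Cells on a straight segment with tiny noise: easiest instance."""
    ls = rng.uniform(size=80)
    X = np.column_stack([ls * 3.0, ls * 1.5])
    X += rng.standard_normal(X.shape) * 0.01
    return Dataset.from_array(X)


class TestInitPool:
    def test_all_members_are_one_edge_trees(self, segment_data):
        cfg = STSConfig(pool_size_L1=5, seed=3)
        pool = init_pool(segment_data, cfg)
        assert len(pool) == 5
        for t in pool.trees:
            assert t.n_vertices == 2
            assert t.edges == ((0, 1),)
            assert validate_tree(t)
        assert all(np.isfinite(s) for s in pool.scores)
        assert pool.sorted_scores() == sorted(pool.scores)

    def test_deterministic_under_seed(self, segment_data):
        cfg = STSConfig(pool_size_L1=4, seed=9)
        p1 = init_pool(segment_data, cfg)
        p2 = init_pool(segment_data, cfg)
        for a, b in zip(p1.trees, p2.trees):
            np.testing.assert_array_equal(a.embedding, b.embedding)
        assert p1.scores == p2.scores

    def test_degenerate_data_raises(self):
        X = np.ones((10, 2))
        d = Dataset(X, [f"c{i}" for i in range(10)], sigma2_hat=1.0)
        with pytest.raises(ValueError):
            init_pool(d, STSConfig(lambda1=1.0, similarity_cutoff_a=0.1))


class TestGrowMoves:
    def test_add_leaf_shape_and_validity(self, rng, small_dataset):
        t = random_tree(rng, 4)
        cfg = STSConfig(lambda3=1.0)
        out = grow_add_leaf(t, small_dataset, cfg, rng)
        assert out.n_vertices == 5
        assert len(out.edges) == 4
        assert validate_tree(out)
        # new vertex placed on some data row
        assert any(np.allclose(out.embedding[4], x) for x in small_dataset.X)

    def test_add_leaf_lambda3_zero_uniform_over_rows(self, rng, small_dataset):
        """With lambda3 = 0 every data row is an equally likely location."""
        t = random_tree(rng, 3)
        cfg = STSConfig(lambda3=0.0)
        counts = np.zeros(small_dataset.n)
        for _ in range(3000):
            out = grow_add_leaf(t, small_dataset, cfg, rng)
            i = int(np.argmin(
                np.linalg.norm(small_dataset.X - out.embedding[3], axis=1)))
            counts[i] += 1
        freq = counts / counts.sum()
        assert np.all(np.abs(freq - 1 / small_dataset.n) < 5 / small_dataset.n)

    def test_add_leaf_dominant_residual_wins_at_large_lambda3(self, rng):
        """One far outlier with lambda3 large: its selection probability
        matches the exact categorical weights e^{lambda3 r*}."""
        t = EmbeddingTree(np.array([[0.0, 0.0], [1.0, 0.0]]), ((0, 1),))
        X = np.vstack([np.column_stack([np.linspace(0, 1, 20),
                                        np.zeros(20)]),
                       [[0.5, 10.0]]])
        d = Dataset.from_array(X)
        cfg = STSConfig(lambda3=8.0)
        hits = 0
        n_draws = 2000
        for _ in range(n_draws):
            out = grow_add_leaf(t, d, cfg, rng)
            if np.allclose(out.embedding[2], [0.5, 10.0]):
                hits += 1
        # exact categorical probability of the outlier row
        r = np.zeros(21)
        r[-1] = 100.0
        w = np.exp(8.0 * r / r.max())
        p_exact = w[-1] / w.sum()
        se = np.sqrt(p_exact * (1 - p_exact) / n_draws)
        assert abs(hits / n_draws - p_exact) < 5 * se + 0.01

    def test_split_edge_midpoint(self, rng):
        t = EmbeddingTree(np.array([[0.0, 0.0], [2.0, 0.0]]), ((0, 1),))
        out = grow_split_edge(t, rng)
        np.testing.assert_allclose(out.embedding[2], [1.0, 0.0])
        assert out.edges == ((0, 2), (1, 2))

    def test_split_preserves_loss(self, rng, small_dataset):
        t = random_tree(rng, 4)
        out = grow_split_edge(t, rng)
        assert validate_tree(out)
        assert len(out.edges) == len(t.edges) + 1
        assert loss(small_dataset, out) == pytest.approx(
            loss(small_dataset, t), abs=1e-10)


class TestTryAdmit:
    def _pool_of(self, trees, data, cfg, capacity=3):
        pool = TreePool(capacity=capacity)
        for t in trees:
            pool = try_admit(pool, t, data, cfg)
        return pool

    def test_empty_pool_always_admits(self, rng, small_dataset):
        cfg = STSConfig(lambda1=1.0, similarity_cutoff_a=0.5)
        pool = try_admit(TreePool(capacity=3), random_tree(rng, 3),
                         small_dataset, cfg)
        assert len(pool) == 1

    def test_identical_candidate_rejected_when_full(self, rng, small_dataset):
        cfg = STSConfig(lambda1=1.0, similarity_cutoff_a=0.5)
        trees = [random_tree(rng, 3) for _ in range(3)]
        pool = self._pool_of(trees, small_dataset, cfg)
        before = list(pool.scores)
        pool = try_admit(pool, trees[0], small_dataset, cfg)  # S1 = 0 <= a
        assert pool.scores == before

    def test_zero_cutoff_replaces_nearest_neighbor(self, rng, small_dataset):
        cfg = STSConfig(lambda1=5.0, similarity_cutoff_a=0.0)
        trees = [random_tree(rng, 3) for _ in range(3)]
        pool = self._pool_of(trees, small_dataset, cfg)
        # build a strictly better candidate: refine a copy of the best tree
        from stsearch import optimize_embedding, tree_similarity
        best_tree, _ = pool.best()
        cand = optimize_embedding(best_tree, small_dataset, cfg)
        s2 = score_S2(small_dataset, cand, cfg)
        if s2 >= min(pool.scores):
            pytest.skip("refinement produced no strict improvement")
        sims = [tree_similarity(cand, t) for t in pool.trees]
        expect_replaced = int(np.argmin(sims))
        new_pool = try_admit(pool, cand, small_dataset, cfg)
        assert new_pool.scores[expect_replaced] == pytest.approx(s2)

    def test_size_mismatch_raises(self, rng, small_dataset):
        cfg = STSConfig(lambda1=1.0, similarity_cutoff_a=0.5)
        pool = self._pool_of([random_tree(rng, 3)], small_dataset, cfg)
        with pytest.raises(ValueError):
            try_admit(pool, random_tree(rng, 4), small_dataset, cfg)


class TestRunSTS:
    def test_noiseless_segment_recovered(self, segment_data, fast_config):
        tree, trace = run_sts(segment_data, fast_config)
        assert validate_tree(tree)
        # near-noiseless straight data: tiny residual, small tree
        assert loss(segment_data, tree) < 0.1
        assert tree.n_vertices <= 4

    def test_deterministic_trace_under_seed(self, segment_data, fast_config):
        t1, tr1 = run_sts(segment_data, fast_config)
        t2, tr2 = run_sts(segment_data, fast_config)
        np.testing.assert_array_equal(t1.embedding, t2.embedding)
        assert t1.edges == t2.edges
        assert tr1.to_json() == tr2.to_json()

    def test_best_scores_decrease_up_to_stopping_size(self, segment_data,
                                                      fast_config):
        tree, trace = run_sts(segment_data, fast_config)
        sizes = sorted(trace.best_s2_per_size)
        scores = [trace.best_s2_per_size[s] for s in sizes]
        # decreasing until the last entry, which may trigger the stop
        for a, b in zip(scores[:-2], scores[1:-1]):
            assert b <= a
        assert trace.final_size == tree.n_vertices

    def test_returned_tree_is_best_of_its_size(self, segment_data,
                                               fast_config):
        tree, trace = run_sts(segment_data, fast_config)
        cfg = fast_config.resolve(segment_data)
        assert score_S2(segment_data, tree, cfg) == pytest.approx(
            trace.best_s2_per_size[tree.n_vertices])
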