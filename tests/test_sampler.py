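import itertools

import numpy as np
import pytest

from alegpr import sampler
from alegpr.data import LabeledSet, UnlabeledPool
from alegpr.hctree import build_tree, initial_pruning
from alegpr.sampler import (
    class_labels_from_targets,
    make_state,
    node_error,
    refine_pruning,
    select_batch,
    total_weighted_error,
    update_node_stats,
)


def state_for(X, labels_by_id, n_classes=2, pruning_size=None, seed=0):
    tree = build_tree(X)
    pruning = initial_pruning(tree, pruning_size or 1)
    scheme = sampler.ClassScheme(kind="quantile-bins", edges=np.array([0.5]))
    st = make_state(tree, pruning, scheme, n_classes=n_classes, seed=seed)
    update_node_stats(st, labels_by_id)
    return st


def all_prunings(node):
    """Every antichain covering the subtree's leaves."""
    if node.is_leaf:
        return [[node]]
    out = [[node]]
    for lp in all_prunings(node.left):
        for rp in all_prunings(node.right):
            out.append(lp + rp)
    return out


class TestClassLabels:
    def test_median_split(self):
        y = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        labels, scheme = class_labels_from_targets(y, k_c=2)
        np.testing.assert_array_equal(labels, [0, 0, 0, 1, 1, 1])
        assert scheme.edges.shape == (1,)

    def test_edges_frozen_across_iterations(self):
        y0 = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        labels0, scheme = class_labels_from_targets(y0, k_c=3)
        # later labels use the same frozen edges regardless of their own spread
        later = scheme.labels_for_targets(np.array([0.1, 2.5, 100.0]))
        np.testing.assert_array_equal(later, [0, 1, 2])
        again = scheme.labels_for_targets(y0)
        np.testing.assert_array_equal(again, labels0)

    def test_all_equal_targets_warn(self):
        with pytest.warns(UserWarning, match="single class"):
            labels, _ = class_labels_from_targets(np.ones(5), k_c=3)
        assert len(set(labels.tolist())) == 1


class TestNodeStats:
    def test_pure_node_collapses_bounds(self, rng):
        X = rng.normal(size=(6, 2))
        st = state_for(X, {i: 0 for i in range(3)})
        root = st.tree.root
        stats = st.stats[root.index]
        assert stats.p[0] == 1.0
        assert stats.lb[0] == stats.ub[0] == 1.0  # d_v = 0 kills the half-width
        assert stats.admissible[0] and not stats.admissible[1]
        assert node_error(st, root) == (0, 0.0)

    def test_unqueried_node_is_vacuous(self, rng):
        X = rng.normal(size=(5, 2))
        st = state_for(X, {})
        for nd in st.tree.nodes:
            stats = st.stats[nd.index]
            np.testing.assert_array_equal(stats.lb, [0.0, 0.0])
            np.testing.assert_array_equal(stats.ub, [1.0, 1.0])
            assert not stats.admissible.any()
            assert node_error(st, nd) == (None, 1.0)

    def test_hand_built_mixed_root(self):
        # four leaves on a line; classes A, A, B for the first three, last unqueried
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        st = state_for(X, {0: 0, 1: 0, 2: 1})
        stats = st.stats[st.tree.root.index]
        assert stats.n_labeled == 3
        assert stats.p[0] == pytest.approx(2 / 3)
        d = 1 / 3
        delta = d / 3 + np.sqrt(d * (2 / 3) * (1 / 3) / 3)
        assert stats.lb[0] == pytest.approx(max(2 / 3 - delta, 0.0))
        assert stats.ub[0] == pytest.approx(min(2 / 3 + delta, 1.0))


class TestAdmissibility:
    def test_beta_two_inequality(self):
        # p_LB = 0.8 vs a rival with p_UB = 0.3: 0.8 > 2*0.3 - 1
        assert (1 - 0.8) < 2 * (1 - 0.3)

    def test_examples_through_state(self, rng):
        X = rng.normal(size=(4, 2))
        st = state_for(X, {0: 0, 1: 0, 2: 0, 3: 0})
        root = st.tree.root
        assert sampler.admissible(st, root, 0)
        assert not sampler.admissible(st, root, 1)
        st2 = state_for(X, {})
        assert not sampler.admissible(st2, st2.tree.root, 0)


class TestRefinePruning:
    def test_uniform_class_stays_coarse(self, rng):
        X = rng.normal(size=(8, 2))
        st = state_for(X, {i: 0 for i in range(8)})
        refine_pruning(st)
        assert total_weighted_error(st) == 0.0
        assert len(st.pruning) == 1  # root already admissible and error-free

    def test_two_class_quartet_splits_root(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        st = state_for(X, {0: 0, 1: 0, 2: 1, 3: 1})
        root_error = st.stats[st.tree.root.index].error
        assert root_error > 0  # mixed classes at the root
        refine_pruning(st)
        assert len(st.pruning) == 2
        assert total_weighted_error(st) == 0.0

    def test_matches_exhaustive_minimum(self, rng):
        for trial in range(60):
            n = int(rng.integers(4, 13))
            X = rng.normal(size=(n, 2))
            labels = {
                int(i): int(rng.integers(0, 3))
                for i in rng.choice(n, size=int(rng.integers(0, n + 1)), replace=False)
            }
            tree = build_tree(X)
            scheme = sampler.ClassScheme(kind="quantile-bins", edges=np.array([0.3, 0.7]))
            st = make_state(tree, [tree.root], scheme, n_classes=3, seed=trial)
            update_node_stats(st, labels)
            refine_pruning(st)
            got = total_weighted_error(st)
            w = lambda nd: nd.n_leaves / tree.n_leaves
            best = min(
                sum(w(nd) * st.stats[nd.index].error for nd in pruning)
                for pruning in all_prunings(tree.root)
            )
            assert got == pytest.approx(best, abs=1e-12)

    def test_error_non_increasing_under_refinement(self, rng):
        X = rng.normal(size=(16, 2))
        tree = build_tree(X)
        scheme = sampler.ClassScheme(kind="quantile-bins", edges=np.array([0.0]))
        st = make_state(tree, initial_pruning(tree, 4), scheme, n_classes=2)
        update_node_stats(st, {int(i): int(i % 2) for i in range(10)})
        before = total_weighted_error(st)
        refine_pruning(st)
        assert total_weighted_error(st) <= before + 1e-12


class TestSelectBatch:
    def test_exhaustion_returns_everything(self, rng):
        X = rng.normal(size=(6, 2))
        st = state_for(X, {}, pruning_size=3)
        batch = select_batch(st, 50)
        assert sorted(batch.ids) == list(range(6))
        assert batch.exhausted

    def test_untouched_node_has_priority(self, rng):
        X = np.vstack([rng.normal(size=(5, 2)), rng.normal(loc=8, size=(5, 2))])
        tree = build_tree(X)
        pruning = initial_pruning(tree, 2)
        scheme = sampler.ClassScheme(kind="quantile-bins", edges=np.array([0.0]))
        st = make_state(tree, pruning, scheme, n_classes=2, seed=0)
        # label every leaf of the first pruning node with one class
        first, second = pruning
        update_node_stats(st, {int(i): 0 for i in first.leaf_ids})
        batch = select_batch(st, second.n_leaves)
        assert set(batch.ids) == set(int(i) for i in second.leaf_ids)

    def test_batch_spreads_over_tied_nodes(self, rng):
        X = rng.normal(size=(12, 2))
        st = state_for(X, {}, pruning_size=4, seed=1)
        batch = select_batch(st, 4)
        start_nodes = {trace[0] for trace in batch.traces}
        assert len(start_nodes) == 4  # one selection per vacuous node first

    def test_determinism(self, rng):
        X = rng.normal(size=(10, 2))
        a = select_batch(state_for(X, {}, pruning_size=3, seed=5), 6)
        b = select_batch(state_for(X, {}, pruning_size=3, seed=5), 6)
        assert a.ids == b.ids and a.traces == b.traces


class TestALIteration:
    def _setup(self, rng, n=30):
        X = rng.normal(size=(n, 3))
        y = X[:, 0] * 2.0
        ids = np.arange(n)
        labeled = LabeledSet(ids[:4] + 1000, rng.normal(size=(4, 3)), np.array([0.0, 1, 2, 3.0]))
        pool = UnlabeledPool(ids, X)
        tree = build_tree(X, ids)
        labels, scheme = class_labels_from_targets(labeled.y, k_c=3)
        st = make_state(tree, initial_pruning(tree, 5), scheme, n_classes=3, seed=0)
        oracle = lambda q: y[np.asarray(q, dtype=int)]
        return st, labeled, pool, oracle

    def test_bookkeeping(self, rng):
        st, labeled, pool, oracle = self._setup(rng)
        st, labeled2, pool2, batch = sampler.al_iteration(st, labeled, pool, oracle, 7)
        assert labeled2.n == labeled.n + 7
        assert pool2.n == pool.n - 7
        assert len(set(batch.ids)) == 7
        assert not set(batch.ids) & set(pool2.ids.tolist())
        assert set(labeled2.ids.tolist()) >= set(batch.ids)

    def test_zero_step_is_noop(self, rng):
        st, labeled, pool, oracle = self._setup(rng)
        st2, labeled2, pool2, batch = sampler.al_iteration(st, labeled, pool, oracle, 0)
        assert labeled2 is labeled and pool2 is pool and batch.ids == []

    def test_full_exhaustion_over_iterations(self, rng):
        st, labeled, pool, oracle = self._setup(rng)
        seen = set()
        for _ in range(6):
            st, labeled, pool, batch = sampler.al_iteration(st, labeled, pool, oracle, 5)
            assert not (seen & set(batch.ids))  # never re-queried
            seen |= set(batch.ids)
        assert pool.n == 0 and len(seen) == 30

    def test_oracle_failure_aborts_atomically(self, rng):
        st, labeled, pool, oracle = self._setup(rng)
        bad_oracle = lambda q: np.full(len(q), np.nan)
        with pytest.raises(RuntimeError):
            sampler.al_iteration(st, labeled, pool, bad_oracle, 3)


def test_confidence_tightens_with_more_labels():
    """The half-width shrinks in expectation as queried count grows."""
    rng = np.random.default_rng(0)
    widths = {n: [] for n in (5, 20, 80)}
    for n in widths:
        for _ in range(200):
            classes = rng.integers(0, 2, size=n)
            counts = np.bincount(classes, minlength=2)
            p = counts / n
            d = 1 - p
            delta = d / n + np.sqrt(d * p * (1 - p) / n)
            widths[n].append(delta.min())
    means = [np.mean(widths[n]) for n in (5, 20, 80)]
    assert means[0] > means[1] > means[2]
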