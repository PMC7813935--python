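"""DIVCLUS-T: inertia, split search, tree growth, elbow, cuts, assignment."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import (
    oracle_best_split,
    oracle_greedy_sequence,
    planted_onehot_groups,
    replay_split_sequence,
)
from diseasetraj.divclus import (
    assign_matrix,
    assign_vector,
    best_monothetic_split,
    cut_tree,
    fit_divclus,
    inertia,
    leaf_criteria,
    order_leaves,
    select_k_elbow,
)


class TestInertia:
    def test_hand_computed_pairs(self):
        assert inertia([(0, 0), (1, 0)]) == pytest.approx(0.5)
        assert inertia([(0,), (1,), (1,)]) == pytest.approx(2 / 3)

    def test_identical_vectors_zero(self):
        assert inertia([(1, 0, 1)] * 7 ) == pytest.approx(0.0)

    def test_empty_is_zero(self):
        assert inertia([]) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.integers(2, 30), st.integers(1, 6))
    def test_matches_definition_on_random_data(self, seed, n, m):
        rng = np.random.default_rng(seed)
        X = rng.random((n, m)) < rng.random(m)
        centroid = X.mean(axis=0)
        direct = float(((X - centroid) ** 2).sum())
        assert inertia(X) == pytest.approx(direct, abs=1e-9)


class TestBestSplit:
    def test_worked_example(self):
        X = [(1, 0, 0), (1, 0, 0), (1, 1, 0), (0, 0, 1), (0, 0, 0)]
        d, red = best_monothetic_split(X)
        assert d == 0
        assert red == pytest.approx(49 / 30)

    def test_unsplittable_identical_cluster(self):
        assert best_monothetic_split([(1, 0)] * 4) == (None, 0.0)

    def test_symmetric_tie_broken_by_lowest_variable(self):
        X = [(0, 0), (0, 0), (1, 1), (1, 1)]
        d, red = best_monothetic_split(X)
        assert d == 0
        assert red == pytest.approx(2.0)

    def test_empty_cluster_raises(self):
        with pytest.raises(ValueError):
            best_monothetic_split(np.zeros((0, 3)))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_agrees_with_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(2, 40)), int(rng.integers(2, 8))
        X = (rng.random((n, m)) < rng.random(m)).astype(int).tolist()
        d, red = best_monothetic_split(X)
        expected = oracle_best_split([tuple(r) for r in X])
        if expected is None or expected[1] <= 0:
            assert red == pytest.approx(0.0, abs=1e-12)
        else:
            assert d == expected[0]
            assert red == pytest.approx(float(expected[1]), rel=1e-12)


class TestFit:
    def test_two_planted_pure_groups(self):
        X = np.array([(0, 1, 0)] * 5 + [(1, 1, 0)] * 5, dtype=bool)
        tree = fit_divclus(X, max_leaves=2)
        assert tree.n_leaves == 2
        assert tree.nodes[0].split_var == 0
        assert tree.inertia_curve[-1] == pytest.approx(0.0, abs=1e-12)

    def test_single_leaf_total_inertia(self):
        X = np.array([(0, 1), (1, 0), (1, 1)], dtype=bool)
        tree = fit_divclus(X, max_leaves=1)
        assert tree.n_leaves == 1
        assert tree.inertia_curve == [pytest.approx(inertia(X))]

    def test_curve_non_increasing(self):
        rng = np.random.default_rng(0)
        X = rng.random((80, 6)) < 0.4
        tree = fit_divclus(X, max_leaves=10)
        assert all(a >= b - 1e-12 for a, b in zip(tree.inertia_curve, tree.inertia_curve[1:]))

    def test_invalid_max_leaves(self):
        with pytest.raises(ValueError):
            fit_divclus(np.zeros((3, 2), dtype=bool), max_leaves=0)

    def test_min_leaf_size_respected(self):
        rng = np.random.default_rng(1)
        X = rng.random((60, 5)) < 0.3
        tree = fit_divclus(X, max_leaves=12, min_leaf_size=5)
        assert all(leaf.n >= 5 for leaf in tree.leaf_nodes())

    def test_inertia_conservation_every_step(self):
        rng = np.random.default_rng(5)
        X = rng.random((120, 7)) < 0.35
        tree = fit_divclus(X, max_leaves=12)
        total = tree.nodes[0].inertia
        reductions = [tree.nodes[nid].reduction for nid in tree.split_sequence]
        leaf_sum = sum(leaf.inertia for leaf in tree.leaf_nodes())
        assert total == pytest.approx(leaf_sum + sum(reductions), rel=1e-9)
        for k, i_k in enumerate(tree.inertia_curve):
            assert i_k == pytest.approx(total - sum(reductions[:k]), rel=1e-9)


class TestElbow:
    def test_worked_curve(self):
        assert select_k_elbow([100, 40, 20, 18, 17]) == 2

    def test_linear_curve_warns_and_picks_two(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="diseasetraj.divclus"):
            assert select_k_elbow([10, 8, 6, 4, 2]) == 2
        assert any("no distinct elbow" in r.message for r in caplog.records)

    def test_override(self):
        assert select_k_elbow([100, 40, 20], override=3) == 3

    def test_short_curve_rejected(self):
        with pytest.raises(ValueError):
            select_k_elbow([5, 3])

    def test_planted_kink_recovered(self):
        X, _ = planted_onehot_groups(4, per_group=60, seed=3)
        tree = fit_divclus(X, max_leaves=7)
        assert select_k_elbow(tree.inertia_curve) == 4


class TestCutAndCriteria:
    @pytest.fixture()
    def tree(self):
        rng = np.random.default_rng(7)
        X = rng.random((100, 6)) < 0.4
        return fit_divclus(X, max_leaves=8), X

    def test_identity_cut(self, tree):
        t, _ = tree
        part = cut_tree(t, t.n_leaves)
        assert sorted(set(part.leaf_to_macro)) == list(range(t.n_leaves))
        np.testing.assert_array_equal(part.leaf_to_macro, np.arange(t.n_leaves))

    def test_single_part(self, tree):
        t, _ = tree
        part = cut_tree(t, 1)
        assert set(part.leaf_to_macro) == {0}

    def test_cut_two_partitions_by_first_split(self, tree):
        t, X = tree
        part = cut_tree(t, 2)
        d1 = t.nodes[0].split_var
        leaves = assign_matrix(t, X)
        macro = part.leaf_to_macro[leaves]
        np.testing.assert_array_equal(macro, X[:, d1].astype(int))

    def test_too_many_parts_rejected(self, tree):
        t, _ = tree
        with pytest.raises(ValueError):
            cut_tree(t, t.n_leaves + 1)

    def test_leaf_criteria_paths(self):
        # depth-2 chain: split on 0, then the 1-side splits on 1
        X = np.array([(0, 0)] * 4 + [(1, 0)] * 2 + [(1, 1)] * 2, dtype=bool)
        tree = fit_divclus(X, max_leaves=3)
        crits = [leaf_criteria(tree, i) for i in range(tree.n_leaves)]
        assert crits[0].inclusion == frozenset() and crits[0].exclusion == {0}
        assert crits[1].inclusion == {0} and crits[1].exclusion == {1}
        assert crits[2].inclusion == {0, 1} and crits[2].exclusion == frozenset()

    def test_members_satisfy_their_leaf_criteria(self, tree):
        t, X = tree
        leaves = assign_matrix(t, X)
        for leaf_id in range(t.n_leaves):
            crit = leaf_criteria(t, leaf_id)
            for v in X[leaves == leaf_id]:
                assert crit.satisfied_by(v)


class TestAssignment:
    def test_build_partition_reproduced(self):
        rng = np.random.default_rng(9)
        X = rng.random((60, 5)) < 0.5
        tree = fit_divclus(X, max_leaves=6)
        leaves = assign_matrix(tree, X)
        for leaf in tree.leaf_nodes():
            np.testing.assert_array_equal(
                np.sort(np.flatnonzero(leaves == leaf.leaf_id)), np.sort(leaf.members)
            )

    def test_total_function_exhaustive(self):
        rng = np.random.default_rng(11)
        m = 6
        X = rng.random((50, m)) < 0.5
        tree = fit_divclus(X, max_leaves=8)
        crits = [leaf_criteria(tree, i) for i in range(tree.n_leaves)]
        for bits in itertools.product([0, 1], repeat=m):
            leaf = assign_vector(tree, bits)
            sat = [i for i, c in enumerate(crits) if c.satisfied_by(bits)]
            assert sat == [leaf]

    def test_dimension_mismatch_rejected(self):
        X = np.zeros((4, 3), dtype=bool)
        X[0, 0] = True
        tree = fit_divclus(X, max_leaves=2)
        with pytest.raises(ValueError):
            assign_vector(tree, (0, 1))


class TestLeafOrder:
    def test_single_split_order(self):
        X = np.array([(0,)] * 3 + [(1,)] * 3, dtype=bool)
        tree = fit_divclus(X, max_leaves=2)
        assert assign_vector(tree, (0,)) == 0
        assert assign_vector(tree, (1,)) == 1

    def test_depth_two_dfs_order(self):
        # root splits on d1=0; the 1-side splits on d2
        X = np.array([(0, 0)] * 4 + [(1, 0)] * 2 + [(1, 1)] * 2, dtype=bool)
        tree = fit_divclus(X, max_leaves=3)
        assert assign_vector(tree, (0, 0)) == 0
        assert assign_vector(tree, (0, 1)) == 0
        assert assign_vector(tree, (1, 0)) == 1
        assert assign_vector(tree, (1, 1)) == 2

    def test_monotone_growth_never_decreases_leaf_id(self):
        rng = np.random.default_rng(13)
        X = rng.random((200, 8)) < 0.3
        tree = fit_divclus(X, max_leaves=12)
        for _ in range(200):
            v = (rng.random(8) < 0.3).astype(int)
            w = v | (rng.random(8) < 0.3).astype(int)  # superset of v
            assert assign_vector(tree, w) >= assign_vector(tree, v)


class TestGreedyOracle:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_full_greedy_sequence_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(3, 40)), int(rng.integers(2, 7))
        X = (rng.random((n, m)) < rng.random(m)).astype(int)
        rows = [tuple(r) for r in X.tolist()]
        tree = fit_divclus(X.astype(bool), max_leaves=6)
        got = replay_split_sequence(tree, rows)
        expected = oracle_greedy_sequence(rows, max_leaves=6)
        assert [(set(r), d) for r, d in got] == [(set(r), d) for r, d in expected]


def test_planted_recovery_exact():
    for k in (2, 3, 4, 5, 6):
        X, labels = planted_onehot_groups(k, per_group=50, seed=k)
        tree = fit_divclus(X, max_leaves=k + 3)
        part = cut_tree(tree, k)
        clusters = part.leaf_to_macro[assign_matrix(tree, X)]
        # the cut-K partition coincides exactly with the planted groups
        mapping = {}
        for c, g in zip(clusters, labels):
            mapping.setdefault(g, set()).add(c)
        assert all(len(v) == 1 for v in mapping.values())
        assert len({next(iter(v)) for v in mapping.values()}) == k
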