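"""Single-tree behavior: impurities, split search, growth, pruning, costs.

The key check is equivalence with a deliberately naive oracle builder that
enumerates every midpoint split with direct-definition impurity arithmetic
and the same tie rules, over exhaustively enumerated tiny datasets.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsartrees import (
    CostMatrix,
    best_split,
    binomial_upper_limit,
    entropy,
    gain_ratio,
    gini_impurity,
    gini_index,
    grow_tree,
    information_gain,
    predict_tree,
    prune_tree,
    tree_from_json,
    tree_to_json,
)
from qsartrees.tree import TreeError, tree_pessimistic_error


class TestImpurities:
    @pytest.mark.parametrize(
        "weights, expected",
        [((10, 0), 0.0), ((5, 5), 0.5), ((2, 6), 0.375)],
    )
    def test_gini_impurity(self, weights, expected):
        assert gini_impurity(weights) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "partition, expected",
        [
            ([(5, 0), (0, 5)], 0.0),
            ([(2, 2), (2, 2)], 0.5),
            ([(4, 1), (1, 4)], 0.32),
        ],
    )
    def test_gini_index(self, partition, expected):
        assert gini_index(partition) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "weights, expected",
        [((10, 0), 0.0), ((5, 5), 1.0), ((1, 3), 0.8112781244591328)],
    )
    def test_entropy_bits(self, weights, expected):
        assert entropy(weights) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "parent, partition, expected",
        [
            ((5, 5), [(5, 0), (0, 5)], 1.0),
            ((4, 4), [(2, 2), (2, 2)], 0.0),
            ((4, 4), [(3, 1), (1, 3)], 1 - 0.8112781244591328),
        ],
    )
    def test_information_gain(self, parent, partition, expected):
        assert information_gain(parent, partition) == pytest.approx(
            expected, abs=1e-12
        )

    def test_gain_ratio_equal_binary_split(self):
        # SplitInfo = 1 for an equal-size binary split, so ratio = IG
        assert gain_ratio((5, 5), [(5, 0), (0, 5)]) == pytest.approx(1.0)
        assert gain_ratio((4, 4), [(2, 2), (2, 2)]) == pytest.approx(0.0)

    def test_zero_weight_errors(self):
        with pytest.raises(TreeError):
            gini_impurity((0, 0))
        with pytest.raises(TreeError):
            entropy((0, 0))
        with pytest.raises(TreeError):
            gini_index([(1, 1), (0, 0)])

    @given(
        st.integers(0, 30),
        st.integers(0, 30),
        st.integers(0, 30),
        st.integers(0, 30),
    )
    @settings(max_examples=200, deadline=None)
    def test_gain_nonnegative_and_purity_iff_zero(self, a, b, c, d):
        if a + b == 0 or c + d == 0 or a + b + c + d == 0:
            return
        parent = (a + c, b + d)
        ig = information_gain(parent, [(a, b), (c, d)])
        assert ig >= -1e-12
        gi = gini_impurity(parent)
        h = entropy(parent)
        pure = parent[0] == 0 or parent[1] == 0
        assert (gi == 0) == pure
        assert (abs(h) < 1e-12) == pure


class TestBestSplit:
    def test_separable_1d_threshold(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([True, True, False, False])
        w = np.ones(4)
        spec = best_split(X, y, w, [0], "gini", chsize=1)
        assert spec.threshold == pytest.approx(2.5)
        assert spec.score == pytest.approx(0.0, abs=1e-12)

    def test_chsize_constraint_rejects_all(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([True, True, False, False])
        assert best_split(X, y, np.ones(4), [0], "gini", chsize=3) is None

    def test_pure_node_returns_none(self):
        X = np.array([[1.0], [2.0]])
        y = np.array([True, True])
        assert best_split(X, y, np.ones(2), [0], "gini") is None

    def test_empty_candidate_set_returns_none(self):
        X = np.array([[1.0], [2.0]])
        y = np.array([True, False])
        assert best_split(X, y, np.ones(2), [], "gini") is None

    def test_tie_breaks_to_lower_feature_index(self):
        # identical columns: both give the same perfect split
        X = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, 4.0]])
        y = np.array([True, True, False, False])
        for crit in ("gini", "gain_ratio"):
            spec = best_split(X, y, np.ones(4), [1, 0], crit)
            assert spec.feature == 0

    def test_flag_partition_is_midpoint_half(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array([True, True, False, False])
        spec = best_split(X, y, np.ones(4), [0], "gain_ratio")
        assert spec.threshold == pytest.approx(0.5)


def oracle_tree(X, y, w, criterion, chsize):
    """Naive reference tree builder: enumerate every candidate split with
    direct-definition arithmetic (plain loops, no cumulative tricks)."""

    def node_counts(rows):
        wrb = sum(w[i] for i in rows if y[i])
        wnrb = sum(w[i] for i in rows if not y[i])
        return wrb, wnrb

    def gini_node(rows):
        wrb, wnrb = node_counts(rows)
        tot = wrb + wnrb
        return 1 - (wrb / tot) ** 2 - (wnrb / tot) ** 2

    def ent(rows):
        wrb, wnrb = node_counts(rows)
        tot = wrb + wnrb
        h = 0.0
        for part in (wrb, wnrb):
            if part > 0:
                h -= part / tot * math.log2(part / tot)
        return h

    def build(rows):
        wrb, wnrb = node_counts(rows)
        if wrb == 0 or wnrb == 0:
            return ("leaf", wrb, wnrb)
        best = None  # (score, feature, threshold, left, right)
        for f in range(X.shape[1]):
            vals = sorted(set(X[i][f] for i in rows))
            for lo, hi in zip(vals[:-1], vals[1:]):
                thr = (lo + hi) / 2
                left = [i for i in rows if X[i][f] <= thr]
                right = [i for i in rows if X[i][f] > thr]
                if len(left) < chsize or len(right) < chsize:
                    continue
                wl = sum(w[i] for i in left)
                wr = sum(w[i] for i in right)
                tot = wl + wr
                if criterion == "gini":
                    score = (wl * gini_node(left) + wr * gini_node(right)) / tot
                    if score >= gini_node(rows) - 1e-12:
                        continue
                    better = best is None or score < best[0] - 1e-12
                else:
                    ig = ent(rows) - (wl * ent(left) + wr * ent(right)) / tot
                    if ig <= 1e-12:
                        continue
                    si = 0.0
                    for part in (wl, wr):
                        si -= part / tot * math.log2(part / tot)
                    score = ig / si
                    better = best is None or score > best[0] + 1e-12
                if better:
                    best = (score, f, thr, left, right)
        if best is None:
            return ("leaf", wrb, wnrb)
        _, f, thr, left, right = best
        return ("split", f, thr, build(left), build(right))

    return build(list(range(len(y))))


def oracle_predict(node, x):
    while node[0] == "split":
        _, f, thr, left, right = node
        node = left if x[f] <= thr else right
    _, wrb, wnrb = node
    return wrb > wnrb  # tie -> NRB


class TestOracleEquivalence:
    @pytest.mark.parametrize("criterion", ["gini", "gain_ratio"])
    def test_exhaustive_two_feature_binary_datasets(self, criterion):
        """Predictions match the naive builder on every 2-feature binary
        dataset with up to 6 samples (multisets over the 8 cells)."""
        cells = list(itertools.product([0.0, 1.0], repeat=3))  # (x1, x2, y)
        grid = [np.array(c[:2]) for c in cells]
        checked = 0
        for n in range(2, 7):
            for combo in itertools.combinations_with_replacement(range(8), n):
                X = np.array([cells[i][:2] for i in combo])
                y = np.array([bool(cells[i][2]) for i in combo])
                if y.all() or (~y).all():
                    continue
                w = np.ones(n)
                mine = grow_tree(X, y, w, criterion=criterion, chsize=1)
                ref = oracle_tree(X, y, w, criterion, chsize=1)
                pred_mine, _ = predict_tree(mine, np.array(grid))
                pred_ref = [oracle_predict(ref, g) for g in grid]
                assert list(pred_mine) == pred_ref, (combo, criterion)
                checked += 1
        assert checked > 1000

    @pytest.mark.parametrize("criterion", ["gini", "gain_ratio"])
    def test_random_small_weighted_datasets(self, criterion):
        """Weighted samples, 3 features, n <= 8, random draws."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = rng.integers(2, 9)
            X = np.round(rng.normal(size=(n, 3)), 1)
            y = rng.random(n) < 0.5
            if y.all() or (~y).all():
                continue
            w = rng.integers(1, 4, size=n).astype(float)
            mine = grow_tree(X, y, w, criterion=criterion, chsize=1)
            ref = oracle_tree(X, y, w, criterion, chsize=1)
            probe = rng.normal(size=(20, 3))
            pred_mine, _ = predict_tree(mine, probe)
            pred_ref = [oracle_predict(ref, x) for x in probe]
            assert list(pred_mine) == pred_ref


class TestGrow:
    def test_separable_data_reaches_zero_training_error(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 1))
        y = X[:, 0] > 0.0
        tree = grow_tree(X, y, criterion="gini", chsize=1)
        pred, _ = predict_tree(tree, X)
        assert (pred == y).all()

    def test_no_duplicate_conflict_implies_zero_error(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 3))
        y = rng.random(30) < 0.4
        tree = grow_tree(X, y, criterion="gain_ratio", chsize=1)
        pred, _ = predict_tree(tree, X)
        assert (pred == y).all()

    def test_identical_features_mixed_labels_single_leaf(self):
        X = np.ones((6, 2))
        y = np.array([True, False, True, False, False, False])
        tree = grow_tree(X, y)
        assert tree.root.is_leaf
        assert tree.root.w_rb == 2 and tree.root.w_nrb == 4

    def test_feature_subsampling_requires_rng(self):
        with pytest.raises(TreeError, match="rng"):
            grow_tree(np.zeros((2, 2)), np.array([True, False]), nfeature=1)

    def test_serialization_round_trip(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 2))
        y = rng.random(20) < 0.5
        tree = grow_tree(X, y, feature_names=("a", "b"))
        back = tree_from_json(tree_to_json(tree))
        p1, _ = predict_tree(tree, X)
        p2, _ = predict_tree(back, X)
        assert (p1 == p2).all()
        assert back.count_nodes() == tree.count_nodes()


class TestPruning:
    def test_zero_error_upper_bound_closed_form(self):
        # CF = 0.25 (pSeverity 75): U(0, 10) = 1 - 0.25**0.1
        assert binomial_upper_limit(0, 10, 0.25) == pytest.approx(
            1 - 0.25**0.1, rel=1e-12
        )
        assert 1 - 0.25**0.1 == pytest.approx(0.1294, abs=5e-5)

    def test_severity_monotonicity(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 3))
        y = rng.random(60) < 0.5
        tree = grow_tree(X, y, criterion="gain_ratio", chsize=2)
        n_mild = prune_tree(tree, 10).count_nodes()
        n_hard = prune_tree(tree, 90).count_nodes()
        assert n_hard <= n_mild <= tree.count_nodes()

    def test_pruning_never_raises_pessimistic_estimate(self):
        rng = np.random.default_rng(7)
        for seed in range(5):
            X = rng.normal(size=(50, 2))
            y = rng.random(50) < 0.5
            tree = grow_tree(X, y, criterion="gain_ratio", chsize=2)
            for ps in (25, 75, 90):
                before = tree_pessimistic_error(tree, ps)
                after = tree_pessimistic_error(prune_tree(tree, ps), ps)
                assert after <= before + 1e-9

    def test_invalid_severity_rejected(self):
        tree = grow_tree(np.zeros((2, 1)), np.array([True, False]))
        with pytest.raises(TreeError):
            prune_tree(tree, 100.0)


class TestCostPrediction:
    def test_minimum_expected_cost_flips_decision(self):
        # leaf (RB 0.4, NRB 0.6): cost(RB as NRB)=2 makes RB the cheaper call
        X = np.ones((10, 1))
        y = np.array([True] * 4 + [False] * 6)
        tree = grow_tree(X, y)
        pred_cost, proba = predict_tree(tree, X[:1], CostMatrix(2.0, 1.0))
        pred_plain, _ = predict_tree(tree, X[:1])
        assert proba[0] == pytest.approx(0.4)
        assert pred_cost[0]  # predicting RB costs 0.6*1, predicting NRB 0.4*2
        assert not pred_plain[0]  # majority NRB without costs

    def test_unit_costs_match_majority(self):
        X = np.ones((10, 1))
        y = np.array([True] * 4 + [False] * 6)
        tree = grow_tree(X, y)
        pred, _ = predict_tree(tree, X[:1], CostMatrix(1.0, 1.0))
        assert not pred[0]

    def test_pure_leaf_ignores_costs(self):
        X = np.ones((5, 1))
        y = np.ones(5, dtype=bool)
        tree = grow_tree(X, y)
        pred, _ = predict_tree(tree, X[:1], CostMatrix(1.0, 100.0))
        assert pred[0]

    def test_cost_matrix_validation(self):
        with pytest.raises(TreeError):
            CostMatrix(0.0, 0.0)
        with pytest.raises(TreeError):
            CostMatrix(-1.0, 1.0)
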