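import itertools

import numpy as np
import pytest

from drgrade import (CartConfig, FeatureVector, LabeledTable, SynthConfig,
                     TreeNode, accuracy, best_split, build_tree, classify,
                     extract_rules, gini, predict, sample_features)
from drgrade.quantify import FEATURE_NAMES


def _table_from_column(values, labels, feature="R_HE"):
    rows = []
    for v, y in zip(values, labels):
        kw = {feature: float(v)} if feature.startswith("R_") \
            else {feature: int(v)}
        rows.append((FeatureVector(**kw), int(y)))
    return LabeledTable(rows=rows)


def _random_table(rng, n):
    rows = []
    for _ in range(n):
        fv = FeatureVector(
            R_HE=float(rng.uniform(0, 0.4)), R_EX=float(rng.uniform(0, 0.1)),
            R_SE=float(rng.uniform(0, 0.4)),
            N_HE=int(rng.integers(0, 10)), N_SE=int(rng.integers(0, 18)),
            N_NV=int(rng.integers(0, 5)))
        rows.append((fv, int(rng.integers(0, 5))))
    return LabeledTable(rows=rows)


class TestGini:
    @pytest.mark.parametrize("counts,expected", [
        ((10, 0, 0, 0, 0), 0.0),
        ((5, 5, 0, 0, 0), 0.5),
        ((1, 1, 1, 1, 1), 0.8),
        ((3, 1, 0, 0, 0), 1 - (0.75 ** 2 + 0.25 ** 2)),
    ])
    def test_values(self, counts, expected):
        assert gini(counts) == pytest.approx(expected)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            gini((0, 0, 0, 0, 0))

    def test_bounded_by_uniform_five_class(self, rng):
        for _ in range(100):
            counts = rng.integers(0, 50, size=5)
            if counts.sum() == 0:
                continue
            assert 0.0 <= gini(counts) <= 0.8


def _brute_force_best_split(X, y):
    """Exhaustive enumeration over all (feature, midpoint) pairs."""
    n = len(y)
    parent = gini(np.bincount(y, minlength=5))
    best = None
    for f in range(X.shape[1]):
        vals = np.unique(X[:, f])
        for a, b in zip(vals[:-1], vals[1:]):
            thr = (a + b) / 2
            left = y[X[:, f] <= thr]
            right = y[X[:, f] > thr]
            dec = parent - (len(left) * gini(np.bincount(left, minlength=5))
                            + len(right) * gini(np.bincount(right,
                                                            minlength=5))) / n
            if dec <= 0:
                continue
            if best is None or dec > best[2] + 1e-15:
                best = (f, thr, dec)
    return best


class TestBestSplit:
    def test_perfectly_separable_midpoint(self):
        table = _table_from_column([0.0, 0.1, 0.2, 0.3], [0, 0, 1, 1])
        f, thr, dec = best_split(table)
        assert FEATURE_NAMES[f] == "R_HE"
        assert thr == pytest.approx(0.15)
        assert dec == pytest.approx(0.5)

    def test_all_constant_features_give_none(self):
        table = _table_from_column([0.2] * 6, [0, 0, 0, 1, 1, 1])
        assert best_split(table) is None

    def test_matches_brute_force_on_small_tables(self, rng):
        for _ in range(30):
            table = _random_table(rng, int(rng.integers(4, 21)))
            X, y = table.to_arrays()
            got = best_split(table)
            want = _brute_force_best_split(X, y)
            if want is None:
                assert got is None
            else:
                assert got[0] == want[0]
                assert got[1] == pytest.approx(want[1])
                assert got[2] == pytest.approx(want[2])


class TestBuildTree:
    def test_pure_table_is_single_leaf(self):
        table = _table_from_column([0.1, 0.2, 0.3], [2, 2, 2])
        tree = build_tree(table)
        assert tree.is_leaf
        assert tree.class_counts == (0, 0, 3, 0, 0)

    def test_max_depth_one_is_a_stump(self):
        table = _table_from_column([0.0, 0.1, 0.2, 0.3], [0, 1, 2, 3])
        tree = build_tree(table, CartConfig(max_depth=1))
        assert not tree.is_leaf
        assert tree.left.is_leaf and tree.right.is_leaf

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            build_tree(LabeledTable(rows=[]))

    def test_deterministic_serialization(self, rng):
        table = _random_table(rng, 60)
        cfg = CartConfig(max_depth=5, min_samples_leaf=2, seed=3)
        t1 = build_tree(table, cfg)
        t2 = build_tree(table, cfg)
        assert t1.to_dict() == t2.to_dict()

    def test_leaf_counts_conserve_table_size(self, rng):
        table = _random_table(rng, 150)
        tree = build_tree(table, CartConfig(max_depth=6))

        def total(node):
            if node.is_leaf:
                return sum(node.class_counts)
            return total(node.left) + total(node.right)

        assert total(tree) == len(table)

    def test_split_never_increases_weighted_gini(self, rng):
        table = _random_table(rng, 200)
        tree = build_tree(table, CartConfig(max_depth=6))

        def counts(node):
            if node.is_leaf:
                return np.array(node.class_counts)
            return counts(node.left) + counts(node.right)

        def check(node):
            if node.is_leaf:
                return
            cl, cr = counts(node.left), counts(node.right)
            parent = gini(cl + cr)
            child = (cl.sum() * gini(cl) + cr.sum() * gini(cr)) \
                / (cl.sum() + cr.sum())
            assert child <= parent + 1e-12
            check(node.left)
            check(node.right)

        check(tree)

    def test_json_round_trip(self, rng, tmp_path):
        from drgrade import load_tree

        tree = build_tree(_random_table(rng, 50), CartConfig(max_depth=4))
        path = tmp_path / "tree.json"
        tree.save(path)
        assert load_tree(path).to_dict() == tree.to_dict()

    def test_agrees_with_sklearn_on_separable_data(self):
        """Cross-check root split and accuracy against an independent CART."""
        sklearn_tree = pytest.importorskip("sklearn.tree")

        cfg = SynthConfig(margin=0.02, seed=5)
        table = LabeledTable.concat(
            [sample_features(s, 200, cfg) for s in range(5)])
        X, y = table.to_arrays()
        ours = build_tree(table, CartConfig(max_depth=8, min_samples_leaf=5))
        theirs = sklearn_tree.DecisionTreeClassifier(
            max_depth=8, min_samples_leaf=5, random_state=0).fit(X, y)
        # same root feature and closely matching threshold
        assert FEATURE_NAMES[theirs.tree_.feature[0]] == ours.feature
        assert ours.threshold == pytest.approx(
            theirs.tree_.threshold[0], abs=0.01)
        ours_acc = np.mean([predict(ours, fv) for fv, _ in table.rows] == y)
        assert ours_acc >= theirs.score(X, y) - 0.01


class TestPredictAndRules:
    def test_single_leaf_constant_prediction(self):
        leaf = TreeNode(class_counts=(1, 0, 4, 0, 0))
        assert predict(leaf, FeatureVector()) == 2
        assert predict(leaf, FeatureVector(R_SE=0.4, N_SE=2)) == 2

    def test_stump_routing(self):
        stump = TreeNode(feature="R_SE", threshold=0.18,
                         left=TreeNode(class_counts=(5, 0, 0, 0, 0)),
                         right=TreeNode(class_counts=(0, 0, 0, 5, 0)))
        assert predict(stump, FeatureVector(R_SE=0.10, N_SE=1)) == 0
        assert predict(stump, FeatureVector(R_SE=0.30, N_SE=1)) == 3

    def test_leaf_tie_breaks_to_lower_severity(self):
        leaf = TreeNode(class_counts=(0, 3, 3, 0, 0))
        assert predict(leaf, FeatureVector()) == 1

    def test_extracted_rule_confidence_from_leaf_fraction(self):
        tree = TreeNode(feature="R_SE", threshold=0.18,
                        left=TreeNode(class_counts=(10, 7, 0, 0, 0)),
                        right=TreeNode(class_counts=(0, 0, 0, 0, 9)))
        rules = extract_rules(tree).rules
        assert rules[0].confidence == pytest.approx(100 * 10 / 17)
        assert rules[1].confidence == pytest.approx(100.0)

    def test_single_pure_leaf_one_rule(self):
        ruleset = extract_rules(TreeNode(class_counts=(0, 0, 0, 0, 4)))
        assert len(ruleset.rules) == 1
        assert ruleset.rules[0].confidence == 100.0
        assert ruleset.rules[0].predicates == ()

    def test_integer_features_render_as_ranges(self, rng):
        # force a path with both bounds on a count feature
        tree = TreeNode(
            feature="N_SE", threshold=0.5,
            left=TreeNode(class_counts=(8, 0, 0, 0, 0)),
            right=TreeNode(feature="N_SE", threshold=15.5,
                           left=TreeNode(class_counts=(0, 6, 0, 0, 0)),
                           right=TreeNode(class_counts=(0, 0, 5, 0, 0))))
        rules = extract_rules(tree).rules
        mid = rules[1].predicates[0]
        assert mid.comparator == "in_int_range"
        assert mid.threshold == (1, 15)

    def test_rules_equal_tree_on_probe_battery(self, rng):
        table = _random_table(rng, 400)
        tree = build_tree(table, CartConfig(max_depth=7, min_samples_leaf=2))
        ruleset = extract_rules(tree)
        for fv, _ in _random_table(rng, 2000).rows:
            assert classify(fv, ruleset).severity == predict(tree, fv)
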