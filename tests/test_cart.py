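"""Classification trees: growing, pruning, prediction, AUC, invariances."""

import numpy as np
import pandas as pd
import pytest

from gesdx import (
    InvalidInputError,
    empirical_auc,
    grow_tree,
    predict_proba,
    prune_tree,
    render_tree,
    tree_auc,
    tree_to_dict,
)
from gesdx.cart import DecisionTree, TreeNode
from gesdx.cohort import feature_frame


def _training_errors(tree, feats, y):
    p = predict_proba(tree, feats)
    return int(np.sum((p >= 0.5).astype(int) != y))


def _leaf_assignments(tree, feats):
    """Leaf identity per subject, independent of cutoff values."""
    probs = predict_proba(tree, feats)
    _, inv = np.unique(probs, return_inverse=True)
    return inv


class TestGrow:
    def test_pure_labels_give_single_node(self, rng):
        feats = pd.DataFrame({"h4": rng.uniform(0, 100, 40)})
        tree = grow_tree(feats, np.zeros(40, int))
        assert tree.root.is_leaf and tree.root.prob == 0.0

    def test_cutoff_lands_in_the_gap(self, rng):
        x = np.concatenate([rng.uniform(0, 8, 100), rng.uniform(12, 30, 100)])
        y = (x > 10).astype(int)
        tree = grow_tree(pd.DataFrame({"h4": x}), y)
        assert tree.root.feature == "h4"
        assert 8.0 < tree.root.threshold < 12.0

    def test_recovers_rule_timepoint_on_synthetic_cohort(self, rule_cohort):
        feats, y = feature_frame(rule_cohort)
        tree = grow_tree(feats, y, min_node_size=10)
        assert tree.root.feature == "h4"
        assert abs(tree.root.threshold - 10.0) <= 2.0

    def test_node_accounting_and_min_size(self, default_cohort):
        feats, y = feature_frame(default_cohort)
        tree = grow_tree(feats, y, min_node_size=10)

        def check(node):
            if node.is_leaf:
                assert node.n >= 10
                return node.n, node.n_cases
            nl, cl = check(node.left)
            nr, cr = check(node.right)
            assert nl + nr == node.n and cl + cr == node.n_cases
            return node.n, node.n_cases

        n, c = check(tree.root)
        assert n == len(y) and c == int(y.sum())

    def test_min_impurity_decrease_respected(self, default_cohort):
        feats, y = feature_frame(default_cohort)
        dec = 20.0
        tree = grow_tree(feats, y, min_node_size=10, min_impurity_decrease=dec)
        from gesdx.cart import _impurity, _subtree_risk

        def walk(node):
            if node.is_leaf:
                return
            gain = _impurity(node.n, node.n_cases, "deviance") - (
                _impurity(node.left.n, node.left.n_cases, "deviance")
                + _impurity(node.right.n, node.right.n_cases, "deviance")
            )
            assert gain >= dec - 1e-9
            walk(node.left)
            walk(node.right)

        walk(tree.root)

    def test_unsplittable_sample_returns_prior_node(self):
        feats = pd.DataFrame({"h4": [1.0, 2.0, 3.0, 4.0]})
        tree = grow_tree(feats, [1, 0, 1, 1], min_node_size=4)
        assert tree.root.is_leaf and tree.root.prob == 0.75

    def test_monotone_feature_transform_preserves_structure(self, rule_cohort):
        feats, y = feature_frame(rule_cohort)
        tree1 = grow_tree(feats, y, min_node_size=10)
        warped = feats.copy()
        for col in ("h1", "h2", "h3", "h4"):
            warped[col] = np.expm1(feats[col] / 25.0)  # strictly increasing
        tree2 = grow_tree(warped, y, min_node_size=10)

        def features_used(node, acc):
            if not node.is_leaf:
                acc.append(node.feature)
                features_used(node.left, acc)
                features_used(node.right, acc)
            return acc

        assert features_used(tree1.root, []) == features_used(tree2.root, [])
        assert np.array_equal(
            _leaf_assignments(tree1, feats), _leaf_assignments(tree2, warped)
        )

    def test_matches_sklearn_root_split(self, rule_cohort):
        from sklearn.tree import DecisionTreeClassifier

        feats, y = feature_frame(rule_cohort)
        clf = DecisionTreeClassifier(
            criterion="log_loss", max_depth=1, min_samples_leaf=10,
            random_state=0,
        ).fit(feats, y)
        tree = grow_tree(feats, y, min_node_size=10)
        assert feats.columns[clf.tree_.feature[0]] == tree.root.feature
        # sklearn stores features as float32, so cutoffs agree only to ~1e-5
        assert clf.tree_.threshold[0] == pytest.approx(
            tree.root.threshold, abs=1e-4
        )


class TestPrune:
    def test_pure_two_leaf_tree_unchanged(self, rng):
        x = np.concatenate([rng.uniform(0, 8, 60), rng.uniform(12, 30, 60)])
        y = (x > 10).astype(int)
        feats = pd.DataFrame({"h4": x})
        tree = grow_tree(feats, y)
        pruned = prune_tree(tree, feats, y, seed=0)
        assert pruned.n_leaves == tree.n_leaves == 2
        assert render_tree(pruned) == render_tree(tree)

    def test_pure_noise_pruned_to_root(self, rng):
        feats = pd.DataFrame({"h4": rng.uniform(0, 100, 200)})
        y = rng.integers(0, 2, 200)
        tree = grow_tree(feats, y, min_node_size=10)
        pruned = prune_tree(tree, feats, y, seed=3)
        assert pruned.n_leaves <= 2  # CV deviance favours the trivial tree

    def test_training_fit_never_improves_with_pruning(self, default_cohort):
        feats, y = feature_frame(default_cohort)
        tree = grow_tree(feats, y, min_node_size=10)
        pruned = prune_tree(tree, feats, y, seed=1)
        assert pruned.n_leaves <= tree.n_leaves
        assert _training_errors(pruned, feats, y) >= _training_errors(
            tree, feats, y
        )

    def test_input_tree_not_modified(self, default_cohort):
        feats, y = feature_frame(default_cohort)
        tree = grow_tree(feats, y, min_node_size=10)
        before = render_tree(tree)
        prune_tree(tree, feats, y, seed=1)
        assert render_tree(tree) == before


class TestPredict:
    @staticmethod
    def _figure_style_tree() -> DecisionTree:
        """Late-retention rule with an age interaction in the discordant
        branch: >10% at 4 h, <53% at 2 h, then age 47.5 splits the leaf
        probabilities 0.85 (younger) vs 0.44 (older)."""
        age_leaf_young = TreeNode(n=60, n_cases=51, depth=3)  # p = 0.85
        age_leaf_old = TreeNode(n=50, n_cases=22, depth=3)  # p = 0.44
        age_node = TreeNode(
            n=110, n_cases=73, depth=2, feature="age", threshold=47.5,
            left=age_leaf_young, right=age_leaf_old,
        )
        concordant = TreeNode(n=97, n_cases=90, depth=2)
        h2_node = TreeNode(
            n=207, n_cases=163, depth=1, feature="h2", threshold=53.0,
            left=age_node, right=concordant,
        )
        low_leaf = TreeNode(n=113, n_cases=18, depth=1)
        root = TreeNode(
            n=320, n_cases=181, depth=0, feature="h4", threshold=10.0,
            left=low_leaf, right=h2_node,
        )
        return DecisionTree(root, ("h2", "h4", "age"))

    def test_single_node_tree_constant(self):
        tree = DecisionTree(TreeNode(n=100, n_cases=62), ("h4",))
        assert predict_proba(tree, {"h4": 3.0}) == pytest.approx(0.62)

    def test_routing_through_age_interaction(self):
        tree = self._figure_style_tree()
        assert predict_proba(
            tree, {"h4": 50.0, "h2": 30.0, "age": 30.0}
        ) == pytest.approx(0.85)
        assert predict_proba(
            tree, {"h4": 50.0, "h2": 30.0, "age": 60.0}
        ) == pytest.approx(0.44)
        # 4-h retention below the cutoff routes to the low-probability leaf
        assert predict_proba(
            tree, {"h4": 5.0, "h2": 30.0, "age": 30.0}
        ) == pytest.approx(18 / 113)

    def test_missing_value_policies(self):
        tree = self._figure_style_tree()
        with pytest.raises(InvalidInputError, match="h4"):
            predict_proba(tree, {"h4": np.nan, "h2": 30.0, "age": 30.0})
        with pytest.raises(InvalidInputError, match="h4"):
            predict_proba(tree, pd.DataFrame({"h2": [30.0], "age": [30.0]}))
        p = predict_proba(
            tree,
            {"h4": np.nan, "h2": 30.0, "age": 30.0},
            missing="larger_child",
        )
        assert p == pytest.approx(0.85)  # 207 > 113 routes right, then young


class TestTreeAUC:
    def test_single_node_is_chance(self, rng):
        feats = pd.DataFrame({"h4": rng.uniform(0, 100, 40)})
        y = rng.integers(0, 2, 40)
        tree = DecisionTree(TreeNode(n=40, n_cases=int(y.sum())), ("h4",))
        assert tree_auc(tree, feats, y) == 0.5

    def test_perfect_tree(self, rng):
        x = np.concatenate([rng.uniform(0, 8, 50), rng.uniform(12, 30, 50)])
        y = (x > 10).astype(int)
        feats = pd.DataFrame({"h4": x})
        tree = grow_tree(feats, y)
        assert tree_auc(tree, feats, y) == 1.0

    def test_two_leaf_closed_form(self):
        # leaf A: 179 cases/28 controls, leaf B: 18 cases/95 controls
        d = np.array([1.0] * 179 + [0.0] * 18)
        c = np.array([1.0] * 28 + [0.0] * 95)
        closed = (179 * 95 + 0.5 * (179 * 28 + 18 * 95)) / (197 * 123)
        assert empirical_auc(d, c) == pytest.approx(closed, abs=1e-12)


def test_tree_exports(default_cohort):
    feats, y = feature_frame(default_cohort)
    tree = grow_tree(feats, y, min_node_size=10)
    text = render_tree(tree)
    assert text.startswith("root n=320")
    d = tree_to_dict(tree)
    assert d["n"] == 320 and "split" in d
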