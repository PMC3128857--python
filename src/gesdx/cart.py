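"""Binary classification trees over retention markers and covariates.

Greedy recursive partitioning: at each node every (variable, cutoff) pair is
scanned — cutoffs at midpoints between adjacent distinct sorted values — and
the split with the largest impurity decrease is taken, subject to a minimum
terminal-node size.  Impurity defaults to the binomial deviance
-2 * sum_k n_k log(n_k / n) (Gini available), the criterion classical tree
software optimises for class outcomes.  The grown tree is then pruned by
weakest-link cost-complexity pruning, with the subtree chosen by k-fold
cross-validated deviance (ties resolved toward the smaller tree).

Because every cutoff is a midpoint and routing compares raw values, a
strictly increasing transform of any feature leaves the tree's structure and
subject routing unchanged — trees are invariant to monotone re-expression of
the markers, unlike the moment-based LDA combination.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .roc import InvalidInputError, empirical_auc

_TOL = 1e-12


@dataclass
class TreeNode:
    n: int
    n_cases: int
    depth: int = 0
    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def prob(self) -> float:
        """Case fraction in the node; the predicted probability at a leaf."""
        return self.n_cases / self.n

    def collapse(self) -> None:
        self.feature = None
        self.threshold = None
        self.left = None
        self.right = None


@dataclass
class DecisionTree:
    """A fitted tree plus the settings it was grown with."""

    root: TreeNode
    feature_names: tuple[str, ...]
    criterion: str = "deviance"
    min_node_size: int = 10

    @property
    def n_leaves(self) -> int:
        return _count_leaves(self.root)

    def copy(self) -> "DecisionTree":
        return DecisionTree(
            copy.deepcopy(self.root),
            self.feature_names,
            self.criterion,
            self.min_node_size,
        )


# ---------------------------------------------------------------------------
# impurity
# ---------------------------------------------------------------------------


def _impurity(n, n1, criterion: str):
    """Count-scaled impurity: deviance -2*sum n_k log(n_k/n), or Gini 2*n1*n0/n."""
    n = np.asarray(n, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n0 = n - n1
    if criterion == "deviance":
        return -2.0 * (xlogy(n1, n1) + xlogy(n0, n0) - xlogy(n, n))
    if criterion == "gini":
        return 2.0 * n1 * n0 / n
    raise InvalidInputError(f"unknown criterion {criterion!r}")


# ---------------------------------------------------------------------------
# growing
# ---------------------------------------------------------------------------


def _coerce_features(features) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), tuple(features.columns)
    x = np.atleast_2d(np.asarray(features, dtype=float))
    return x, tuple(f"x{i + 1}" for i in range(x.shape[1]))

def _best_split(x: np.ndarray, y: np.ndarray, min_leaf: int, criterion: str):
    """Best (gain, feature index, cutoff) over all admissible splits, or None.

    Ties go to the smallest feature index, then the smallest cutoff.
    """
    n = y.size
    n1 = int(y.sum())
    parent = float(_impurity(n, n1, criterion))
    best = None
    for j in range(x.shape[1]):
        xs = x[:, j]
        order = np.argsort(xs, kind="stable")
        xs_s, ys_s = xs[order], y[order]
        cum1 = np.cumsum(ys_s)
        sizes = np.arange(min_leaf, n - min_leaf + 1)
        if sizes.size == 0:
            continue
        ok = xs_s[sizes - 1] < xs_s[sizes]  # split only between distinct values
        sizes = sizes[ok]
        if sizes.size == 0:
            continue
        n1_left = cum1[sizes - 1]
        gain = parent - (
            _impurity(sizes, n1_left, criterion)
            + _impurity(n - sizes, n1 - n1_left, criterion)
        )
        k = int(np.argmax(gain))  # first max => smallest cutoff
        if best is None or gain[k] > best[0] + _TOL:
            cutoff = 0.5 * (xs_s[sizes[k] - 1] + xs_s[sizes[k]])
            best = (float(gain[k]), j, float(cutoff))
    return best


def grow_tree(
    features,
    labels,
    min_node_size: int = 10,
    min_impurity_decrease: float = 0.0,
    criterion: str = "deviance",
) -> DecisionTree:
    """Greedy recursive partitioning of a binary outcome.

    ``min_node_size`` bounds every terminal node from below; splitting stops
    when no split satisfies it or none decreases the impurity by at least
    ``min_impurity_decrease``.  All-constant features yield the single-node
    tree carrying the prior case fraction.
    """
    x, names = _coerce_features(features)
    y = np.asarray(labels).astype(int).ravel()
    if x.shape[0] != y.size:
        raise InvalidInputError("features/labels length mismatch")
    if not set(np.unique(y)) <= {0, 1}:
        raise InvalidInputError("labels must be binary 0/1")
    if min_node_size < 1:
        raise InvalidInputError("min_node_size must be >= 1")
    if y.size < 2:
        raise InvalidInputError("need at least 2 subjects to grow a tree")
    # fewer than 2*min_node_size subjects admits no split: the root becomes a
    # leaf carrying the prior case fraction
    if not np.isfinite(x).all():
        raise InvalidInputError("features must be finite (no missing values)")

    def build(rows: np.ndarray, depth: int) -> TreeNode:
        yy = y[rows]
        node = TreeNode(n=rows.size, n_cases=int(yy.sum()), depth=depth)
        if node.n_cases in (0, node.n) or node.n < 2 * min_node_size:
            return node
        found = _best_split(x[rows], yy, min_node_size, criterion)
        if found is None:
            return node
        gain, j, cutoff = found
        if gain <= _TOL or gain < min_impurity_decrease - _TOL:
            return node
        node.feature = names[j]
        node.threshold = cutoff
        go_left = x[rows, j] < cutoff
        node.left = build(rows[go_left], depth + 1)
        node.right = build(rows[~go_left], depth + 1)
        return node

    root = build(np.arange(y.size), 0)
    return DecisionTree(root, names, criterion, min_node_size)


# ---------------------------------------------------------------------------
# cost-complexity pruning
# ---------------------------------------------------------------------------


def _count_leaves(node: TreeNode) -> int:
    if node.is_leaf:
        return 1
    return _count_leaves(node.left) + _count_leaves(node.right)


def _subtree_risk(node: TreeNode, criterion: str) -> float:
    if node.is_leaf:
        return float(_impurity(node.n, node.n_cases, criterion))
    return _subtree_risk(node.left, criterion) + _subtree_risk(
        node.right, criterion
    )


def _link_strengths(node: TreeNode, criterion: str, out: list) -> None:
    """Collect (g, node) for every internal node, where g is the per-leaf cost
    saving of collapsing it: (R(t) - R(subtree)) / (leaves - 1)."""
    if node.is_leaf:
        return
    r_node = float(_impurity(node.n, node.n_cases, criterion))
    g = (r_node - _subtree_risk(node, criterion)) / (_count_leaves(node) - 1)
    out.append((g, node))
    _link_strengths(node.left, criterion, out)
    _link_strengths(node.right, criterion, out)


def _prune_at_alpha(root: TreeNode, alpha: float, criterion: str) -> None:
    """Collapse weakest links, in place, while their strength is <= alpha."""
    while not root.is_leaf:
        links: list = []
        _link_strengths(root, criterion, links)
        g_min = min(g for g, _ in links)
        if g_min > alpha + _TOL:
            break
        for g, node in links:
            if g <= g_min + _TOL and not node.is_leaf:
                node.collapse()


def cc_alpha_sequence(tree: DecisionTree) -> list[float]:
    """Weakest-link alpha sequence of the tree (starting at 0 = full tree)."""
    root = copy.deepcopy(tree.root)
    alphas = [0.0]
    while not root.is_leaf:
        links: list = []
        _link_strengths(root, tree.criterion, links)
        g_min = min(g for g, _ in links)
        alphas.append(max(g_min, alphas[-1]))
        for g, node in links:
            if g <= g_min + _TOL and not node.is_leaf:
                node.collapse()
    return alphas


def _stratified_folds(y: np.ndarray, n_folds: int, rng) -> np.ndarray:
    """Fold assignment per subject, stratified by label."""
    fold = np.empty(y.size, dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(idx.size)]
        fold[idx] = np.arange(idx.size) % n_folds
    return fold


def _holdout_deviance(root: TreeNode, x, names, y) -> float:
    """-2 log-likelihood of held-out labels under Laplace-smoothed leaf
    probabilities (n1 + 0.5)/(n + 1); smoothing keeps a held-out point in a
    pure opposite-class leaf from contributing an infinite deviance."""
    total = 0.0
    for row, yi in zip(x, y):
        node = root
        while not node.is_leaf:
            j = names.index(node.feature)
            node = node.left if row[j] < node.threshold else node.right
        p = (node.n_cases + 0.5) / (node.n + 1.0)
        total += -2.0 * (np.log(p) if yi == 1 else np.log1p(-p))
    return total


def prune_tree(
    tree: DecisionTree,
    features,
    labels,
    n_folds: int = 10,
    min_node_size: int | None = None,
    seed: int = 0,
    min_impurity_decrease: float = 0.0,
) -> DecisionTree:
    """Cost-complexity pruning with the subtree picked by cross-validation.

    Candidate penalties are taken between consecutive weakest-link alphas of
    the grown tree; for each, every CV fold grows its own tree on the
    remaining subjects, prunes it at that penalty and scores the held-out
    fold's deviance.  The penalty minimising total CV deviance wins, with
    ties resolved toward the larger penalty (the smaller tree).  The result
    is a pruned subtree of the input; the input is not modified.
    """
    if min_node_size is None:
        min_node_size = tree.min_node_size
    pruned = tree.copy()
    if pruned.root.is_leaf:
        return pruned
    x, names = _coerce_features(features)
    y = np.asarray(labels).astype(int).ravel()

    seq = cc_alpha_sequence(tree)
    cands = [0.0]
    for a, b in zip(seq[1:], seq[2:]):
        cands.append(float(np.sqrt(a * b)) if a > 0 else b / 2.0)
    cands.append(seq[-1] * 1.5 + 1e-9)
    cands = sorted(set(cands))

    rng = np.random.default_rng(seed)
    fold = _stratified_folds(y, n_folds, rng)
    cv_dev = np.zeros(len(cands))
    for f in range(n_folds):
        train = fold != f
        if y[train].min() == y[train].max() or train.sum() < 2 * min_node_size:
            continue
        sub = grow_tree(
            pd.DataFrame(x[train], columns=names),
            y[train],
            min_node_size=min_node_size,
            min_impurity_decrease=min_impurity_decrease,
            criterion=tree.criterion,
        )
        work = sub.root  # prune incrementally over ascending candidates
        for k, alpha in enumerate(cands):
            _prune_at_alpha(work, alpha, tree.criterion)
            cv_dev[k] += _holdout_deviance(work, x[~train], list(names), y[~train])

    best = cv_dev.min()
    k = int(np.flatnonzero(cv_dev <= best + 1e-9)[-1])  # ties: larger alpha
    _prune_at_alpha(pruned.root, cands[k], tree.criterion)
    return pruned


# ---------------------------------------------------------------------------
# prediction and export
# ---------------------------------------------------------------------------


def predict_proba(tree: DecisionTree, features, missing: str = "error"):
    """Terminal-node case fraction for each subject.

    Routing: value < cutoff goes left.  Missing (NaN) split values raise by
    default; ``missing="larger_child"`` routes them to the child with more
    training subjects.
    """
    if isinstance(features, (pd.Series, dict)):
        features = pd.DataFrame([features])
        squeeze = True
    else:
        squeeze = False
    if isinstance(features, pd.DataFrame):
        cols = set(features.columns)
        used = _used_features(tree.root)
        missing_cols = used - cols
        if missing_cols:
            raise InvalidInputError(
                f"record lacks split variable(s): {sorted(missing_cols)}"
            )
        x = features[list(tree.feature_names)].to_numpy(dtype=float)
        names = list(tree.feature_names)
    else:
        x = np.atleast_2d(np.asarray(features, dtype=float))
        names = list(tree.feature_names)

    out = np.empty(x.shape[0])
    for i, row in enumerate(x):
        node = tree.root
        while not node.is_leaf:
            v = row[names.index(node.feature)]
            if np.isnan(v):
                if missing == "error":
                    raise InvalidInputError(
                        f"missing value for split variable {node.feature!r}"
                    )
                node = (
                    node.left if node.left.n >= node.right.n else node.right
                )
                continue
            node = node.left if v < node.threshold else node.right
        out[i] = node.prob
    return float(out[0]) if squeeze else out


def _used_features(node: TreeNode) -> set:
    if node.is_leaf:
        return set()
    return (
        {node.feature} | _used_features(node.left) | _used_features(node.right)
    )


def tree_auc(tree: DecisionTree, features, labels) -> float:
    """Empirical AUC of the tree's predicted probabilities (subjects sharing a
    terminal node tie and contribute the half weight)."""
    y = np.asarray(labels).astype(int).ravel()
    p = predict_proba(tree, features)
    return empirical_auc(p[y == 1], p[y == 0])


def render_tree(tree: DecisionTree) -> str:
    """Indented one-node-per-line text: rule, subject count, case fraction."""
    lines: list[str] = []

    def walk(node: TreeNode, rule: str, indent: int) -> None:
        tag = " *" if node.is_leaf else ""
        lines.append(
            f"{'  ' * indent}{rule} n={node.n} p_case={node.prob:.3f}{tag}"
        )
        if not node.is_leaf:
            walk(node.left, f"{node.feature} < {node.threshold:g}", indent + 1)
            walk(node.right, f"{node.feature} >= {node.threshold:g}", indent + 1)

    walk(tree.root, "root", 0)
    return "\n".join(lines)


def tree_to_dict(tree: DecisionTree) -> dict:
    """Machine-readable nested structure of the fitted tree."""

    def walk(node: TreeNode) -> dict:
        d = {"n": node.n, "n_cases": node.n_cases, "p_case": round(node.prob, 6)}
        if not node.is_leaf:
            d["split"] = {"feature": node.feature, "cutoff": node.threshold}
            d["left"] = walk(node.left)
            d["right"] = walk(node.right)
        return d

    return walk(tree.root)
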