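"""Feature selection over (gene, structure) features.

Three complementary procedures identify the features that carry the
decoding signal:

* **Random-KNN support** — many random feature subsets of varying size
  are drawn; for each, the leave-one-out k-NN accuracy is computed.  The
  *support* of a feature f is the mean accuracy of all sampled
  classifiers whose subset contains f (its *multiplicity* M is how many
  such classifiers were sampled).
* **Random-forest mean decrease Gini (MDG)** — an ensemble of CART
  trees, each grown on a bootstrap sample and a random feature subset;
  a feature's importance is the impurity decrease it contributes,
  summed within a tree and averaged over the trees that contained it.
* **Descriptive CART tree** — a single unconstrained binary tree grown
  to purity with entropy-based information gain, as an interpretable
  picture of how features segregate the classes.

Selected feature sets are evaluated either by LOO k-NN accuracy
(:func:`top_n_evaluation`) or by a depth- and leaf-size-regularized
decision tree under stratified k-fold cross-validation
(:func:`evaluate_pruned_tree`).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .decoder import loo_predict
from .errors import FeatureError
from .normalization import FeatureMatrix

__all__ = [
    "rknn_support",
    "top_n_evaluation",
    "rf_importance",
    "evaluate_pruned_tree",
    "build_cart_tree",
    "DecisionTree",
    "TreeNode",
    "gini_impurity",
    "entropy",
]


# ---------------------------------------------------------------------------
# Random-KNN support


def _loo_accuracy_stack(diffs: np.ndarray, codes: np.ndarray, subset) -> float:
    """LOO 1-NN accuracy on a feature subset, from precomputed per-feature
    squared-difference matrices (diffs: n_features x n x n)."""
    d = diffs[list(subset)].sum(axis=0)
    np.fill_diagonal(d, np.inf)
    return float(np.mean(codes[d.argmin(axis=1)] == codes))


def _sample_subsets(n_features, n_subsets, size_range, rng):
    lo, hi = size_range
    sizes = rng.integers(lo, hi + 1, size=n_subsets)
    return [tuple(rng.choice(n_features, size=s, replace=False)) for s in sizes]


def rknn_support(
    data: FeatureMatrix,
    n_subsets: int = 10_000,
    size_range: tuple[int, int | None] = (1, None),
    k: int = 1,
    seed: int | None = 0,
    subsets: list[tuple[int, ...]] | None = None,
) -> pd.DataFrame:
    """Random-KNN support of every feature.

    Subset sizes are uniform over ``size_range`` (default 1..n_features)
    and features are drawn uniformly without replacement.  An explicit
    ``subsets`` list (tuples of feature indices) bypasses sampling, e.g.
    to enumerate the full subset lattice of a small problem.

    Returns a frame indexed by feature with columns ``multiplicity``
    (M, the number of sampled classifiers containing the feature) and
    ``support`` (their mean LOO accuracy), sorted by support descending.
    Features never sampled get M = 0, support NaN, and a warning.
    """
    X, codes = data.X, pd.factorize(data.y)[0]
    p = X.shape[1]
    lo, hi = size_range
    hi = p if hi is None else hi
    if not 1 <= lo <= hi <= p:
        raise FeatureError(f"size_range {size_range} outside [1, {p}]")
    rng = np.random.default_rng(seed)
    if subsets is None:
        subsets = _sample_subsets(p, n_subsets, (lo, hi), rng)

    fast = k == 1
    if fast:
        diffs = (X[:, None, :] - X[None, :, :]) ** 2  # (n, n, p)
        diffs = np.moveaxis(diffs, 2, 0).copy()  # (p, n, n)
    acc_sum = np.zeros(p)
    mult = np.zeros(p, dtype=int)
    for sub in subsets:
        if fast:
            acc = _loo_accuracy_stack(diffs, codes, sub)
        else:
            acc = float(np.mean(loo_predict(X[:, list(sub)], data.y, k=k) == data.y))
        idx = list(sub)
        acc_sum[idx] += acc
        mult[idx] += 1
    with np.errstate(invalid="ignore"):
        support = np.where(mult > 0, acc_sum / np.maximum(mult, 1), np.nan)
    if (mult == 0).any():
        missing = [data.feature_names[i] for i in np.flatnonzero(mult == 0)]
        warnings.warn(f"features never sampled (support undefined): {missing}")
    out = pd.DataFrame(
        {"multiplicity": mult, "support": support},
        index=pd.Index(data.feature_names, name="feature"),
    )
    return out.sort_values("support", ascending=False, kind="stable")


def top_n_evaluation(
    data: FeatureMatrix,
    support: pd.DataFrame | None = None,
    n_grid: list[int] | None = None,
    k: int = 1,
    feature_list: list[str] | None = None,
) -> pd.DataFrame:
    """LOO accuracy of the top-n-by-support feature subsets.

    With ``feature_list`` given, evaluates that explicit subset instead
    (one row, n = len(list)).  Returns a frame with columns ``n``,
    ``features`` and ``accuracy``.
    """
    rows = []
    if feature_list is not None:
        sub = data.select(feature_list)
        acc = float(np.mean(loo_predict(sub.X, sub.y, k=k) == sub.y))
        rows.append((len(feature_list), tuple(feature_list), acc))
    else:
        if support is None or not n_grid:
            raise FeatureError("need a support table and a nonempty n_grid")
        ranked = list(support.sort_values("support", ascending=False, kind="stable").index)
        for n in n_grid:
            if n > len(ranked):
                raise FeatureError(f"n={n} exceeds {len(ranked)} features")
            feats = ranked[:n]
            sub = data.select(feats)
            acc = float(np.mean(loo_predict(sub.X, sub.y, k=k) == sub.y))
            rows.append((n, tuple(feats), acc))
    return pd.DataFrame(rows, columns=["n", "features", "accuracy"])


# ---------------------------------------------------------------------------
# Random-forest mean decrease Gini


def _tree_impurity_decrease(tree, n_features_sub: int) -> np.ndarray:
    """Per-feature impurity decrease of one fitted sklearn tree,
    normalized by the root sample weight (so a root split of a balanced
    two-class node into pure halves scores 0.5)."""
    t = tree.tree_
    w = t.weighted_n_node_samples
    dec = np.zeros(n_features_sub)
    for i in range(t.node_count):
        left, right = t.children_left[i], t.children_right[i]
        if left == -1:
            continue
        drop = w[i] * t.impurity[i] - w[left] * t.impurity[left] - w[right] * t.impurity[right]
        dec[t.feature[i]] += drop / w[0]
    return dec


def rf_importance(
    data: FeatureMatrix,
    n_trees: int = 1000,
    size_range: tuple[int, int | None] = (1, None),
    bootstrap: bool = True,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Mean decrease in Gini impurity over a random-forest ensemble.

    Each tree draws a feature subset of uniform random size in
    ``size_range`` and (by default) a bootstrap resample of the mice,
    and is grown with Gini splits.  A feature's MDG is its impurity
    decrease summed within each tree, averaged over the trees whose
    feature subset contained it.

    Returns a frame indexed by feature with ``mdg`` and ``n_trees``
    (ensemble members containing the feature), sorted by MDG descending.
    """
    if n_trees < 1:
        raise FeatureError("n_trees must be >= 1")
    X, y = data.X, data.y
    n, p = X.shape
    lo, hi = size_range
    hi = p if hi is None else hi
    if not 1 <= lo <= hi <= p:
        raise FeatureError(f"size_range {size_range} outside [1, {p}]")
    rng = np.random.default_rng(seed)
    dec_sum = np.zeros(p)
    containing = np.zeros(p, dtype=int)
    for _ in range(n_trees):
        size = int(rng.integers(lo, hi + 1))
        feats = rng.choice(p, size=size, replace=False)
        rows = rng.integers(0, n, size=n) if bootstrap else np.arange(n)
        yb = y[rows]
        containing[feats] += 1
        if len(set(yb)) < 2:
            continue  # degenerate bootstrap: nothing to split
        clf = DecisionTreeClassifier(
            criterion="gini", random_state=int(rng.integers(2**31 - 1))
        )
        clf.fit(X[np.ix_(rows, feats)], yb)
        dec_sum[feats] += _tree_impurity_decrease(clf, len(feats))
    with np.errstate(invalid="ignore"):
        mdg = np.where(containing > 0, dec_sum / np.maximum(containing, 1), 0.0)
    out = pd.DataFrame(
        {"mdg": mdg, "n_trees": containing},
        index=pd.Index(data.feature_names, name="feature"),
    )
    return out.sort_values("mdg", ascending=False, kind="stable")


def evaluate_pruned_tree(
    data: FeatureMatrix,
    feature_subset: list[str] | None = None,
    max_depth: int = 4,
    n_folds: int = 10,
    min_group: int = 3,
    seed: int | None = 0,
) -> float:
    """Cross-validated accuracy of a regularized CART tree.

    Gini trees of depth <= ``max_depth`` with at least ``min_group``
    mice per leaf, under stratified ``n_folds``-fold cross-validation;
    the returned accuracy is the mean over held-out folds.  Classes
    with fewer members than folds fall back to unstratified folding
    with a warning.
    """
    if n_folds < 2 or max_depth < 1:
        raise FeatureError("need n_folds >= 2 and max_depth >= 1")
    sub = data.select(feature_subset) if feature_subset else data
    X, y = sub.X, sub.y
    min_class = min(Counter(y).values())
    if min_class < n_folds:
        warnings.warn(
            f"smallest class has {min_class} < {n_folds} members; "
            "folding without stratification"
        )
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    else:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in splitter.split(X, y):
        clf = DecisionTreeClassifier(
            criterion="gini",
            max_depth=max_depth,
            min_samples_leaf=min_group,
            random_state=seed,
        )
        clf.fit(X[train], y[train])
        accs.append(float(np.mean(clf.predict(X[test]) == y[test])))
    return float(np.mean(accs))


# ---------------------------------------------------------------------------
# Descriptive CART tree with information gain


def gini_impurity(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(1.0 - np.sum(p**2))


def entropy(labels: np.ndarray) -> float:
    """Shannon entropy of a label vector, in bits."""
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


@dataclass
class TreeNode:
    depth: int
    counts: dict
    feature: str | None = None  # None for leaves
    threshold: float | None = None
    left: "TreeNode | None" = None  # samples with value <= threshold
    right: "TreeNode | None" = None
    label: object = None
    impure: bool = False
    gain: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def n(self) -> int:
        return sum(self.counts.values())


@dataclass
class DecisionTree:
    root: TreeNode
    feature_names: list[str]
    criterion: str = "information_gain"

    @property
    def depth(self) -> int:
        def d(node):
            return node.depth if node.is_leaf else max(d(node.left), d(node.right))

        return d(self.root)

    def predict_one(self, x: np.ndarray):
        node = self.root
        name_to_idx = {f: i for i, f in enumerate(self.feature_names)}
        while not node.is_leaf:
            node = node.left if x[name_to_idx[node.feature]] <= node.threshold else node.right
        return node.label

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.array([self.predict_one(row) for row in np.asarray(X, dtype=float)])

    def render(self) -> str:
        """Indented text rendering; the <= branch is the left branch."""
        lines: list[str] = []

        def walk(node: TreeNode, prefix: str) -> None:
            if node.is_leaf:
                tag = " (impure)" if node.impure else ""
                lines.append(f"{prefix}leaf: {node.label} {dict(node.counts)}{tag}")
            else:
                lines.append(
                    f"{prefix}[{node.feature} <= {node.threshold:.4g}] "
                    f"(n={node.n}, gain={node.gain:.3f} bits)"
                )
                walk(node.left, prefix + "  ")
                walk(node.right, prefix + "  ")

        walk(self.root, "")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        rows = []

        def walk(node: TreeNode, node_id: int, parent: int) -> int:
            rows.append(
                {
                    "node": node_id,
                    "parent": parent,
                    "depth": node.depth,
                    "feature": node.feature,
                    "threshold": node.threshold,
                    "n": node.n,
                    "label": node.label,
                    "impure": node.impure,
                }
            )
            next_id = node_id + 1
            if not node.is_leaf:
                next_id = walk(node.left, next_id, node_id)
                next_id = walk(node.right, next_id, node_id)
            return next_id

        walk(self.root, 0, -1)
        return pd.DataFrame(rows)


def _best_split(X: np.ndarray, y: np.ndarray):
    """Best (feature, threshold) by information gain; candidates are
    midpoints between consecutive sorted unique values; ties go to the
    lower feature index, then the lower threshold."""
    parent = entropy(y)
    n = len(y)
    best = None  # (gain, feature, threshold)
    for j in range(X.shape[1]):
        vals = np.unique(X[:, j])
        if len(vals) < 2:
            continue
        thresholds = (vals[:-1] + vals[1:]) / 2.0
        order = np.argsort(X[:, j], kind="stable")
        y_sorted = y[order]
        x_sorted = X[order, j]
        for t in thresholds:
            n_left = int(np.searchsorted(x_sorted, t, side="right"))
            gain = (
                parent
                - (n_left / n) * entropy(y_sorted[:n_left])
                - ((n - n_left) / n) * entropy(y_sorted[n_left:])
            )
            if best is None or gain > best[0] + 1e-12:
                best = (gain, j, float(t))
    return best


def build_cart_tree(data: FeatureMatrix, criterion: str = "information_gain") -> DecisionTree:
    """Grow an unconstrained binary CART tree with information-gain splits.

    The tree is grown to purity: splitting stops only when a node is
    single-class or its feature vectors are indistinguishable (in which
    case the leaf takes the majority label — lexicographically first on
    a tie — and is flagged impure).
    """
    if criterion != "information_gain":
        raise FeatureError(f"unsupported criterion: {criterion!r}")
    if len(data) == 0:
        raise FeatureError("cannot build a tree on empty data")
    X, y = data.X, data.y
    names = data.feature_names

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        yy = y[idx]
        counts = dict(sorted(Counter(yy.tolist()).items(), key=lambda kv: str(kv[0])))
        if len(counts) == 1:
            return TreeNode(depth=depth, counts=counts, label=yy[0])
        split = _best_split(X[idx], yy)
        if split is None or split[0] <= 1e-12:
            majority = max(counts.items(), key=lambda kv: (kv[1], str(kv[0])))[0]
            warnings.warn(
                f"indistinguishable feature vectors with conflicting labels {counts}; "
                "leaf takes the majority label"
            )
            return TreeNode(depth=depth, counts=counts, label=majority, impure=True)
        gain, j, t = split
        mask = X[idx, j] <= t
        return TreeNode(
            depth=depth,
            counts=counts,
            feature=names[j],
            threshold=t,
            gain=gain,
            left=grow(idx[mask], depth + 1),
            right=grow(idx[~mask], depth + 1),
        )

    return DecisionTree(root=grow(np.arange(len(y)), 0), feature_names=names)
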