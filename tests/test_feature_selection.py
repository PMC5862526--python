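from itertools import chain, combinations

import numpy as np
import pytest

from iegdecode.decoder import loo_predict
from iegdecode.errors import FeatureError
from iegdecode.feature_selection import (
    build_cart_tree,
    entropy,
    evaluate_pruned_tree,
    gini_impurity,
    rf_importance,
    rknn_support,
    top_n_evaluation,
)


def all_nonempty_subsets(p):
    return list(
        chain.from_iterable(combinations(range(p), r) for r in range(1, p + 1))
    )


class TestRknnSupport:
    def test_single_feature_support_is_its_own_loo_accuracy(self, fm_factory):
        rng = np.random.default_rng(1)
        fm = fm_factory(rng.normal(size=(12, 1)), rng.choice(list("ab"), 12))
        table = rknn_support(fm, n_subsets=50, size_range=(1, 1), seed=0)
        own = float(np.mean(loo_predict(fm.X, fm.y) == fm.y))
        assert table.loc["f0", "support"] == pytest.approx(own)
        assert table.loc["f0", "multiplicity"] == 50

    def test_exhaustive_three_feature_lattice_matches_brute_force(self, fm_factory):
        rng = np.random.default_rng(2)
        fm = fm_factory(rng.normal(size=(10, 3)), rng.choice(list("ab"), 10))
        subsets = all_nonempty_subsets(3)  # the 7 nonempty subsets
        table = rknn_support(fm, subsets=subsets, seed=0)
        # independent brute force: accuracy of each subset by direct loop
        acc = {}
        for sub in subsets:
            pred = loo_predict(fm.X[:, list(sub)], fm.y)
            acc[sub] = float(np.mean(pred == fm.y))
        for f in range(3):
            containing = [a for sub, a in acc.items() if f in sub]
            assert table.loc[f"f{f}", "support"] == pytest.approx(np.mean(containing))
            assert table.loc[f"f{f}", "multiplicity"] == 4

    def test_multiplicities_sum_to_total_subset_sizes(self, sparse_fm):
        fm, _ = sparse_fm
        table = rknn_support(fm, n_subsets=500, seed=3)
        rng = np.random.default_rng(3)
        sizes = rng.integers(1, 26, size=500)
        assert table["multiplicity"].sum() == sizes.sum()

    def test_sole_signal_feature_has_maximal_support(self, fm_factory):
        rng = np.random.default_rng(6)
        y = np.repeat(list("ab"), 8)
        signal = np.where(y == "a", 0.0, 5.0) + rng.normal(0, 0.3, 16)
        X = np.column_stack([signal, rng.normal(size=(16, 3))])
        fm = fm_factory(X, y)
        table = rknn_support(fm, n_subsets=800, seed=7)
        assert table["support"].idxmax() == "f0"

    def test_unsampled_features_warned_and_flagged(self, fm_factory):
        rng = np.random.default_rng(8)
        fm = fm_factory(rng.normal(size=(8, 5)), rng.choice(list("ab"), 8))
        with pytest.warns(UserWarning, match="never sampled"):
            table = rknn_support(fm, n_subsets=2, size_range=(1, 1), seed=0)
        assert (table["multiplicity"] == 0).sum() >= 3
        assert table.loc[table["multiplicity"] == 0, "support"].isna().all()

    def test_support_bounded_by_sampled_accuracies(self, sparse_fm):
        fm, _ = sparse_fm
        subsets = [tuple(range(5)), tuple(range(10, 15))]
        table = rknn_support(fm, subsets=subsets)
        accs = [
            float(np.mean(loo_predict(fm.X[:, list(s)], fm.y) == fm.y))
            for s in subsets
        ]
        sampled = table[table["multiplicity"] > 0]["support"]
        assert sampled.between(min(accs), max(accs)).all()


class TestTopN:
    def test_full_set_equals_full_feature_accuracy(self, sparse_fm):
        fm, _ = sparse_fm
        support = rknn_support(fm, n_subsets=300, seed=1)
        out = top_n_evaluation(fm, support=support, n_grid=[25])
        full = float(np.mean(loo_predict(fm.X, fm.y) == fm.y))
        assert out["accuracy"].iloc[0] == pytest.approx(full)

    def test_explicit_feature_list_bypasses_ranking(self, sparse_fm):
        fm, truth = sparse_fm
        from iegdecode.schema import feature_name

        informative = sorted(feature_name(g, s) for g, s in truth.informative_mask)
        out = top_n_evaluation(fm, feature_list=informative)
        assert out["n"].iloc[0] == 5
        assert out["accuracy"].iloc[0] >= 0.9

    def test_informative_subset_not_worse_than_all_features(self, sparse_fm):
        fm, truth = sparse_fm
        from iegdecode.schema import feature_name

        informative = sorted(feature_name(g, s) for g, s in truth.informative_mask)
        top = top_n_evaluation(fm, feature_list=informative)["accuracy"].iloc[0]
        full = float(np.mean(loo_predict(fm.X, fm.y) == fm.y))
        assert top >= full - 0.1

    def test_empty_grid_rejected(self, sparse_fm):
        with pytest.raises(FeatureError):
            top_n_evaluation(sparse_fm[0], support=None, n_grid=[])


class TestRfImportance:
    def test_perfect_splitter_has_maximal_mdg(self, fm_factory):
        rng = np.random.default_rng(9)
        y = np.repeat(list("ab"), 10)
        X = np.column_stack(
            [np.where(y == "a", 0.0, 10.0), rng.normal(size=(20, 4))]
        )
        fm = fm_factory(X, y)
        table = rf_importance(fm, n_trees=200, seed=0)
        assert table["mdg"].idxmax() == "f0"

    def test_root_split_of_balanced_node_scores_half(self, fm_factory):
        # class counts {a:2, b:2}, one clean feature: gini 0.5 -> 0
        fm = fm_factory([[0.0], [0.1], [1.0], [1.1]], ["a", "a", "b", "b"])
        table = rf_importance(fm, n_trees=50, bootstrap=False, seed=0)
        assert table.loc["f0", "mdg"] == pytest.approx(0.5)

    def test_single_class_data_has_zero_importance(self, fm_factory):
        fm = fm_factory(np.random.default_rng(0).normal(size=(8, 3)), ["a"] * 8)
        table = rf_importance(fm, n_trees=30, seed=0)
        assert (table["mdg"] == 0).all()

    def test_label_permutation_flattens_importances(self, sparse_fm):
        # under shuffled labels no feature should dominate consistently
        from iegdecode.permutation import permute_labels

        fm, _ = sparse_fm
        top = []
        for s in range(10):
            shuffled = permute_labels(fm, seed=s)
            table = rf_importance(shuffled, n_trees=100, seed=s)
            top.append(table["mdg"].idxmax())
        assert len(set(top)) > 3  # no stable winner on noise

    def test_informative_features_dominate(self, sparse_fm):
        from iegdecode.schema import feature_name

        fm, truth = sparse_fm
        table = rf_importance(fm, n_trees=400, seed=1)
        informative = {feature_name(g, s) for g, s in truth.informative_mask}
        assert set(table.index[:5]) == informative


class TestPrunedTree:
    def test_perfectly_separable_single_feature(self, fm_factory):
        X = np.concatenate([np.zeros(15), np.ones(15) * 9]).reshape(-1, 1)
        y = np.repeat(list("ab"), 15)
        fm = fm_factory(X, y)
        assert evaluate_pruned_tree(fm, n_folds=5, min_group=3, seed=0) == 1.0

    def test_zero_effect_data_scores_near_chance(self, null_fm):
        fm, _ = null_fm
        with pytest.warns(UserWarning, match="stratification"):
            acc = evaluate_pruned_tree(fm, n_folds=10, seed=0)
        assert acc < 0.3  # 10 classes; chance is 0.1

    def test_depth_and_fold_bounds(self, null_fm):
        with pytest.raises(FeatureError):
            evaluate_pruned_tree(null_fm[0], n_folds=1)
        with pytest.raises(FeatureError):
            evaluate_pruned_tree(null_fm[0], max_depth=0)


class TestCartTree:
    def test_single_class_gives_lone_leaf(self, fm_factory):
        fm = fm_factory([[0.0], [1.0], [2.0]], ["a", "a", "a"])
        tree = build_cart_tree(fm)
        assert tree.root.is_leaf and tree.root.label == "a" and tree.depth == 0

    def test_one_dimensional_two_cluster_split(self, fm_factory):
        fm = fm_factory([[0.0], [1.0], [10.0], [11.0]], ["A", "A", "B", "B"])
        tree = build_cart_tree(fm)
        root = tree.root
        assert not root.is_leaf
        assert 1.0 < root.threshold < 10.0
        assert root.gain == pytest.approx(1.0)  # one full bit
        assert root.left.label == "A" and root.right.label == "B"

    def test_every_mouse_routes_to_a_pure_leaf(self, sparse_fm):
        fm, _ = sparse_fm
        tree = build_cart_tree(fm)
        assert (tree.predict(fm.X) == fm.y).all()

    def test_conflicting_duplicates_flagged_impure(self, fm_factory):
        fm = fm_factory([[1.0], [1.0], [1.0]], ["a", "a", "b"])
        with pytest.warns(UserWarning, match="conflicting"):
            tree = build_cart_tree(fm)
        assert tree.root.is_leaf and tree.root.impure and tree.root.label == "a"

    def test_render_and_frame_are_consistent(self, fm_factory):
        fm = fm_factory([[0.0, 5.0], [1.0, 5.0], [10.0, 0.0], [11.0, 0.0]], list("AABB"))
        tree = build_cart_tree(fm)
        frame = tree.to_frame()
        assert (frame["parent"] < frame["node"]).iloc[1:].all()
        assert tree.render().count("leaf") == (frame["feature"].isna()).sum()

    def test_every_split_has_positive_gain(self, sparse_fm):
        # weighted child impurity never exceeds the parent's: gain >= 0,
        # and the tree records the gain it achieved at every split
        fm, _ = sparse_fm
        tree = build_cart_tree(fm)

        def walk(node):
            if node.is_leaf:
                return
            labels = np.array(
                [lab for lab, c in node.counts.items() for _ in range(c)]
            )
            lw = node.left.n / node.n
            weighted_children = lw * entropy(
                np.array([l for l, c in node.left.counts.items() for _ in range(c)])
            ) + (1 - lw) * entropy(
                np.array([l for l, c in node.right.counts.items() for _ in range(c)])
            )
            assert node.gain == pytest.approx(entropy(labels) - weighted_children)
            assert node.gain > 0
            walk(node.left)
            walk(node.right)

        walk(tree.root)


class TestImpurityHelpers:
    def test_hand_values(self):
        assert gini_impurity(np.array(["a", "a", "b", "b"])) == pytest.approx(0.5)
        assert gini_impurity(np.array(["a", "a"])) == 0.0
        assert entropy(np.array(["a", "a", "b", "b"])) == pytest.approx(1.0)
        assert entropy(np.array(["a", "b", "c", "d"])) == pytest.approx(2.0)
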