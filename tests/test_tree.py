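"""Gain-ratio decision tree: split criterion, induction, feature selection."""

import warnings

import numpy as np
import pytest

from pneumotex.tree import (GainRatioTree, GainRatioTreeSelector,
                            TreeGrowthParams, best_split, build_tree,
                            class_entropy, predict_tree, selected_features)


def entropy_bits(labels):
    _, counts = np.unique(labels, return_counts=True)
    f = counts / len(labels)
    return float(-(f * np.log2(f)).sum())


def gain_ratio_oracle(values, labels):
    """Exhaustive midpoint enumeration with the textbook formulas."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    parent = entropy_bits(labels)
    distinct = np.unique(values)
    best = None
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        thr = (lo + hi) / 2
        left = values <= thr
        n_l, n = left.sum(), len(labels)
        child = (n_l / n) * entropy_bits(labels[left]) \
            + ((n - n_l) / n) * entropy_bits(labels[~left])
        gain = parent - child
        if gain <= 1e-15:
            continue
        si = -(n_l / n) * np.log2(n_l / n) - ((n - n_l) / n) * np.log2((n - n_l) / n)
        ratio = gain / si
        if best is None or ratio > best[1] + 1e-15:
            best = (thr, ratio)
    return best


class TestClassEntropy:
    def test_examples(self):
        assert class_entropy([0, 0, 0, 0]) == 0.0
        assert class_entropy([0, 0, 1, 1]) == 1.0
        assert class_entropy([0, 0, 0, 1]) == pytest.approx(0.811278, abs=1e-6)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            class_entropy([])


class TestBestSplit:
    def test_perfect_balanced_split(self):
        thr, ratio = best_split([1, 2, 3, 4], [0, 0, 1, 1])
        assert thr == 2.5
        assert ratio == pytest.approx(1.0)

    def test_alternating_labels_match_oracle(self):
        got = best_split([1, 2, 3, 4], [0, 1, 0, 1])
        want = gain_ratio_oracle([1, 2, 3, 4], [0, 1, 0, 1])
        assert got == pytest.approx(want)

    def test_constant_column_gives_no_split(self):
        assert best_split([5, 5, 5, 5], [0, 1, 0, 1]) is None

    @pytest.mark.parametrize("trial", range(15))
    def test_matches_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(4, 51))
        values = rng.choice(rng.normal(size=max(2, n // 2)), size=n)
        labels = rng.integers(0, 2, size=n)
        got = best_split(values, labels)
        want = gain_ratio_oracle(values, labels)
        if want is None:
            assert got is None
        else:
            assert got[0] == pytest.approx(want[0])
            assert got[1] == pytest.approx(want[1], rel=1e-12)


class TestBuildTree:
    def test_perfectly_separating_feature_gives_single_split(self):
        X = np.array([[0.1, 5.0], [0.2, 1.0], [0.9, 4.0], [0.8, 2.0]])
        y = np.array([0, 0, 1, 1])
        tree = build_tree(X, y, TreeGrowthParams(min_samples_leaf=1))
        assert not tree.is_leaf and tree.feature == 0
        assert tree.left.is_leaf and tree.right.is_leaf

    def test_single_class_gives_leaf(self):
        tree = build_tree(np.random.default_rng(0).random((5, 2)), np.zeros(5))
        assert tree.is_leaf

    def test_beats_best_single_feature_stump(self, rng):
        X = rng.normal(size=(20, 3))
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0.5)).astype(int)
        tree = build_tree(X, y, TreeGrowthParams(min_samples_leaf=1))
        tree_acc = (predict_tree(tree, X) == y).mean()
        stump_acc = 0.0
        for j in range(3):  # exhaustive threshold search per feature
            for thr in np.unique(X[:, j]):
                for sign in (0, 1):
                    pred = (X[:, j] > thr).astype(int) ^ sign
                    stump_acc = max(stump_acc, (pred == y).mean())
        assert tree_acc >= stump_acc

    def test_noise_feature_does_not_displace_perfect_root_split(self, rng):
        X = np.column_stack([
            np.concatenate([rng.uniform(0, 0.4, 15), rng.uniform(0.6, 1.0, 15)]),
            rng.normal(size=30),
        ])
        y = np.repeat([0, 1], 15)
        tree = build_tree(X, y)
        assert tree.feature == 0

    def test_training_samples_land_in_matching_leaves(self, rng):
        X = rng.normal(size=(40, 4))
        y = (X[:, 1] + 0.3 * rng.normal(size=40) > 0).astype(int)
        tree = build_tree(X, y)
        for row, pred in zip(X, predict_tree(tree, X)):
            node = tree
            while not node.is_leaf:
                node = node.left if row[node.feature] <= node.threshold else node.right
            counts = node.class_counts
            assert counts.get(pred, 0) == max(counts.values())


class TestSelectedFeatures:
    def test_dedup_and_order(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0],
                      [0.0, 0.5], [1.0, 0.5]])
        y = np.array([0, 1, 1, 0, 0, 1])  # needs both features
        tree = build_tree(X, y, TreeGrowthParams(min_samples_leaf=1))
        sel = selected_features(tree)
        assert sel == sorted(set(sel))
        assert set(sel) <= {0, 1}

    def test_leaf_only_tree_warns_and_returns_empty(self):
        tree = build_tree(np.zeros((4, 2)), np.zeros(4))
        with pytest.warns(UserWarning, match="no internal nodes"):
            assert selected_features(tree) == []


class TestSklearnWrappers:
    def test_classifier_fit_predict(self, rng):
        X = rng.normal(size=(30, 3))
        y = (X[:, 0] > 0).astype(int)
        model = GainRatioTree().fit(X, y)
        assert (model.predict(X) == y).mean() == 1.0
        assert 0 in model.selected_features_

    def test_selector_keeps_informative_columns_across_seeds(self):
        """With signal planted in columns 1 and 3, the branch set should
        include at least one of them in the majority of seeded datasets."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 40
            y = np.repeat([0, 1], n // 2)
            X = rng.normal(size=(n, 5))
            X[:, 1] += 1.5 * y
            X[:, 3] -= 1.2 * y
            sel = GainRatioTreeSelector().fit(X, y)
            if {1, 3} & set(np.flatnonzero(sel.get_support())):
                hits += 1
        assert hits > 5

    def test_selector_transform_drops_columns(self, rng):
        X = rng.normal(size=(20, 4))
        y = (X[:, 2] > 0).astype(int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = GainRatioTreeSelector().fit(X, y)
        assert sel.transform(X).shape[1] == len(sel.estimator_.selected_features_)
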