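"""Decision-tree feature selection for continuous features.

A C4.5-lineage tree: binary splits ``feature <= threshold`` on continuous
attributes, chosen by gain ratio (information gain divided by split
information, both in bits), grown top-down until a node is pure or a stopping
rule fires.  The tree doubles as a feature selector: the distinct features
tested at its internal nodes form the selected subset.

No pruning is applied by default — selection wants the grown tree's branch
set — but pessimistic pruning would only ever shrink the subset.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "class_entropy",
    "best_split",
    "Node",
    "TreeGrowthParams",
    "build_tree",
    "selected_features",
    "predict_tree",
    "GainRatioTree",
    "GainRatioTreeSelector",
]


def class_entropy(labels: np.ndarray) -> float:
    """Shannon entropy of the label distribution, in bits."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("cannot compute entropy of an empty label set")
    _, counts = np.unique(labels, return_counts=True)
    f = counts / labels.size
    return float(-(f * np.log2(f)).sum())


def _split_entropy(labels: np.ndarray, left: np.ndarray) -> tuple[float, float]:
    """(weighted child entropy, split information) for a boolean partition."""
    n = labels.size
    n_l = int(left.sum())
    n_r = n - n_l
    h = (n_l / n) * class_entropy(labels[left]) + (n_r / n) * class_entropy(labels[~left])
    w = np.array([n_l / n, n_r / n])
    split_info = float(-(w * np.log2(w)).sum())
    return h, split_info


def best_split(values: np.ndarray, labels: np.ndarray
               ) -> tuple[float, float] | None:
    """Best gain-ratio threshold for one continuous feature column.

    Candidate thresholds are midpoints between consecutive sorted distinct
    values.  Only splits with strictly positive information gain are
    considered; among those the gain ratio is maximized, ties going to the
    smallest threshold.  Returns ``None`` when no split qualifies (e.g. all
    values identical).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.size != labels.size:
        raise ValueError("values and labels must have equal length")
    if values.size < 2:
        return None
    distinct = np.unique(values)
    if distinct.size < 2:
        return None
    parent_h = class_entropy(labels)
    best: tuple[float, float] | None = None
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        thr = 0.5 * (lo + hi)
        left = values <= thr
        child_h, split_info = _split_entropy(labels, left)
        gain = parent_h - child_h
        if gain <= 1e-15 or split_info <= 0:
            continue
        ratio = gain / split_info
        if best is None or ratio > best[1] + 1e-15:
            best = (thr, ratio)
    return best


@dataclasses.dataclass
class Node:
    """Tree node; ``feature is None`` marks a leaf."""

    class_counts: dict
    prediction: object
    feature: int | None = None
    threshold: float | None = None
    left: "Node | None" = None
    right: "Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        d = {"class_counts": {str(k): int(v) for k, v in self.class_counts.items()},
             "prediction": np.asarray(self.prediction).item()}
        if not self.is_leaf:
            d.update(feature=int(self.feature), threshold=float(self.threshold),
                     left=self.left.to_dict(), right=self.right.to_dict())
        return d


@dataclasses.dataclass(frozen=True)
class TreeGrowthParams:
    """Stopping rules: defaults favour a fully grown (selection-ready) tree."""

    min_samples_leaf: int = 2
    max_depth: int = 10
    min_gain: float = 1e-6  # bits


def _majority(labels: np.ndarray):
    classes, counts = np.unique(labels, return_counts=True)
    return classes[np.argmax(counts)]  # ties -> smallest class label


def build_tree(X: np.ndarray, y: np.ndarray,
               params: TreeGrowthParams = TreeGrowthParams()) -> Node:
    """Top-down induction; deterministic (lowest feature index wins ties)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)

    def grow(idx: np.ndarray, depth: int) -> Node:
        labels = y[idx]
        classes, counts = np.unique(labels, return_counts=True)
        node = Node(class_counts=dict(zip(classes.tolist(), counts.tolist())),
                    prediction=_majority(labels))
        if (classes.size == 1 or depth >= params.max_depth
                or idx.size < 2 * params.min_samples_leaf):
            return node
        parent_h = class_entropy(labels)
        best_choice = None  # (feature, threshold, ratio, gain)
        for j in range(X.shape[1]):
            found = best_split(X[idx, j], labels)
            if found is None:
                continue
            thr, ratio = found
            left_n = int((X[idx, j] <= thr).sum())
            if left_n < params.min_samples_leaf or idx.size - left_n < params.min_samples_leaf:
                # re-scan this column for the best qualifying threshold
                found = _best_split_min_leaf(X[idx, j], labels, params.min_samples_leaf)
                if found is None:
                    continue
                thr, ratio = found
            if best_choice is None or ratio > best_choice[2] + 1e-15:
                child_h, _ = _split_entropy(labels, X[idx, j] <= thr)
                best_choice = (j, thr, ratio, parent_h - child_h)
        if best_choice is None or best_choice[3] < params.min_gain:
            return node
        j, thr, _, _ = best_choice
        left = idx[X[idx, j] <= thr]
        right = idx[X[idx, j] > thr]
        node.feature = j
        node.threshold = thr
        node.left = grow(left, depth + 1)
        node.right = grow(right, depth + 1)
        return node

    return grow(np.arange(y.size), depth=0)


def _best_split_min_leaf(values: np.ndarray, labels: np.ndarray,
                         min_leaf: int) -> tuple[float, float] | None:
    """Like :func:`best_split` but skipping thresholds leaving a tiny child."""
    values = np.asarray(values, dtype=float)
    distinct = np.unique(values)
    if distinct.size < 2:
        return None
    parent_h = class_entropy(labels)
    best = None
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        thr = 0.5 * (lo + hi)
        left = values <= thr
        n_l = int(left.sum())
        if n_l < min_leaf or values.size - n_l < min_leaf:
            continue
        child_h, split_info = _split_entropy(labels, left)
        gain = parent_h - child_h
        if gain <= 1e-15 or split_info <= 0:
            continue
        ratio = gain / split_info
        if best is None or ratio > best[1] + 1e-15:
            best = (thr, ratio)
    return best


def selected_features(tree: Node) -> list[int]:
    """Distinct feature indices at internal nodes, in index order."""
    found: set[int] = set()

    def walk(node: Node) -> None:
        if node.is_leaf:
            return
        found.add(int(node.feature))
        walk(node.left)
        walk(node.right)

    walk(tree)
    if not found:
        warnings.warn("tree has no internal nodes; selected subset is empty",
                      stacklevel=2)
    return sorted(found)


def predict_tree(tree: Node, X: np.ndarray) -> np.ndarray:
    """Route each row down the tree to its leaf's majority class."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = []
    for row in X:
        node = tree
        while not node.is_leaf:
            node = node.left if row[node.feature] <= node.threshold else node.right
        out.append(node.prediction)
    return np.asarray(out)


class GainRatioTree(ClassifierMixin, BaseEstimator):
    """sklearn-style classifier wrapper around the gain-ratio tree.

    Fitted attributes
    -----------------
    tree_ : Node
        Root of the grown tree.
    selected_features_ : list of int
        Features tested at internal nodes (the selection result).
    """

    def __init__(self, min_samples_leaf: int = 2, max_depth: int = 10,
                 min_gain: float = 1e-6):
        self.min_samples_leaf = min_samples_leaf
        self.max_depth = max_depth
        self.min_gain = min_gain

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        params = TreeGrowthParams(self.min_samples_leaf, self.max_depth,
                                  self.min_gain)
        self.tree_ = build_tree(X, y, params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.selected_features_ = selected_features(self.tree_)
        return self

    def predict(self, X):
        check_is_fitted(self, "tree_")
        X = check_array(X)
        return predict_tree(self.tree_, X)

    def to_json(self) -> str:
        check_is_fitted(self, "tree_")
        return json.dumps({"tree": self.tree_.to_dict(),
                           "selected_features": self.selected_features_})


class GainRatioTreeSelector(SelectorMixin, BaseEstimator):
    """Feature selector: keep the columns the gain-ratio tree branches on."""

    def __init__(self, min_samples_leaf: int = 2, max_depth: int = 10,
                 min_gain: float = 1e-6):
        self.min_samples_leaf = min_samples_leaf
        self.max_depth = max_depth
        self.min_gain = min_gain

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.estimator_ = GainRatioTree(self.min_samples_leaf, self.max_depth,
                                        self.min_gain).fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "estimator_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.estimator_.selected_features_] = True
        return mask
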