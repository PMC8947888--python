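"""Cross-validated classifier evaluation: pooled scores, confusion metrics,
ROC and AUC.

The protocol is stratified k-fold (k = 5 by default): samples are shuffled
within class under a fixed seed and dealt round-robin into folds, each fold
is scored by a model trained on the remaining k - 1 folds, and every sample's
held-out score is pooled into one vector before metrics are computed.  Pooled
(rather than fold-averaged) metrics keep the confusion table interpretable as
one 2x2 table over the whole cohort.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import roc_curve

from .svm import KernelSVC

__all__ = [
    "stratified_kfold",
    "cross_validate",
    "CVMetrics",
    "confusion_metrics",
    "ROCCurve",
    "roc_auc",
    "evaluate_conditions",
]


def stratified_kfold(labels: np.ndarray, k: int = 5, seed: int = 0) -> np.ndarray:
    """Fold index (0..k-1) per sample; class counts per fold differ by <= 1.

    Raises
    ------
    ValueError
        If any class has fewer than ``k`` members.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds = np.empty(labels.size, dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise ValueError(f"class {cls!r} has {idx.size} samples, fewer than k={k}")
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds


def cross_validate(X: np.ndarray, y: np.ndarray, estimator=None, k: int = 5,
                   seed: int = 0, folds: np.ndarray | None = None) -> np.ndarray:
    """Pooled held-out scores, one per sample, in original sample order.

    ``estimator`` is any sklearn-style classifier exposing
    ``score_samples``/``predict_proba`` (defaults to a linear
    :class:`~pneumotex.svm.KernelSVC`); it is cloned and refitted per fold,
    so per-fold feature standardization happens inside ``fit``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if estimator is None:
        estimator = KernelSVC(kernel="linear")
    if folds is None:
        folds = stratified_kfold(y, k=k, seed=seed)
    scores = np.full(y.size, np.nan)
    for f in np.unique(folds):
        train, test = folds != f, folds == f
        try:
            model = clone(estimator).fit(X[train], y[train])
        except Exception as exc:
            raise RuntimeError(f"training failed in fold {f}: {exc}") from exc
        if hasattr(model, "score_samples"):
            scores[test] = model.score_samples(X[test])
        else:
            scores[test] = model.predict_proba(X[test])[:, 1]
    assert not np.isnan(scores).any(), "every sample must be scored exactly once"
    return scores


@dataclasses.dataclass(frozen=True)
class CVMetrics:
    """Pooled 2x2 confusion summary at a fixed score threshold."""

    accuracy: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int


def confusion_metrics(y_true: np.ndarray, scores: np.ndarray,
                      threshold: float = 0.5) -> CVMetrics:
    """Accuracy, sensitivity (TPR over patients) and specificity (TNR).

    A score >= ``threshold`` counts as a positive (patient) call.
    """
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    if set(np.unique(y_true)) - {0, 1}:
        raise ValueError("labels must be 0/1")
    if not (y_true == 1).any() or not (y_true == 0).any():
        raise ValueError("both classes must be present")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (y_true == 1)).sum())
    fp = int(((pred == 1) & (y_true == 0)).sum())
    tn = int(((pred == 0) & (y_true == 0)).sum())
    fn = int(((pred == 0) & (y_true == 1)).sum())
    return CVMetrics(
        accuracy=(tp + tn) / y_true.size,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


@dataclasses.dataclass(frozen=True)
class ROCCurve:
    """Threshold-sweep ROC points (monotone, (0,0) to (1,1)) and their AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> ROCCurve:
    """ROC curve via descending threshold sweep; AUC by the trapezoidal rule.

    The trapezoidal area equals the Mann-Whitney concordance probability with
    half credit for ties.
    """
    y_true = np.asarray(y_true).astype(int)
    if not (y_true == 1).any() or not (y_true == 0).any():
        raise ValueError("both classes must be present")
    fpr, tpr, thr = roc_curve(y_true, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def evaluate_conditions(features: pd.DataFrame, feature_columns: list[str],
                        subset_columns: list[str] | None,
                        kernels: tuple[str, ...] = ("gaussian", "linear", "polynomial"),
                        k: int = 5, seed: int = 0, C: float = 1.0,
                        q: int = 3, sigma2: float = 0.1) -> pd.DataFrame:
    """Metric grid over kernel x {full feature set, selected subset}.

    One seeded fold assignment is reused across all conditions so that rows
    are comparable.  Returns a tidy DataFrame with accuracy/sensitivity/
    specificity/AUC per condition (proportions in [0, 1]).
    """
    y = features["label"].to_numpy().astype(int)
    folds = stratified_kfold(y, k=k, seed=seed)
    conditions = [("full", feature_columns)]
    if subset_columns:
        conditions.append(("subset", subset_columns))
    rows = []
    for kernel in kernels:
        est = KernelSVC(kernel=kernel, q=q, sigma2=sigma2, C=C)
        for cond_name, cols in conditions:
            X = features[cols].to_numpy(dtype=float)
            scores = cross_validate(X, y, est, folds=folds)
            m = confusion_metrics(y, scores)
            roc = roc_auc(y, scores)
            rows.append({
                "kernel": kernel, "feature_set": cond_name,
                "n_features": len(cols),
                "accuracy": m.accuracy, "sensitivity": m.sensitivity,
                "specificity": m.specificity, "auc": roc.auc,
            })
    return pd.DataFrame(rows)
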