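"""Soft-margin kernel SVM with a calibrated [0, 1] output score.

Three kernels are supported:

    linear       K(x, y) = x . y
    polynomial   K(x, y) = (x . y + 1)^q          (q = 3 default)
    gaussian     K(x, y) = exp(-||x - y||^2 / (2 sigma^2))   (sigma^2 = 0.1)

The dual problem is solved by a deterministic SMO — most-violating-pair
working-set selection, analytic two-variable updates — so identical data
always yields an identical model.  Raw decision values are mapped into (0, 1)
by a Platt-style sigmoid fitted on the training decision values; a sample
scoring >= 0.5 is classified as positive (diseased).

Features are standardized to train-set mean/SD inside ``fit`` by default:
a fixed Gaussian width is meaningless without a fixed feature scale.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "KernelSpec",
    "kernel_value",
    "kernel_matrix",
    "KernelSVC",
    "dual_objective",
]

_KERNELS = ("linear", "polynomial", "gaussian")


@dataclasses.dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus its hyperparameters."""

    kind: str = "linear"
    q: int = 3          # polynomial degree
    sigma2: float = 0.1  # Gaussian width sigma^2

    def __post_init__(self) -> None:
        if self.kind not in _KERNELS:
            raise ValueError(f"kernel kind must be one of {_KERNELS}")
        if not (isinstance(self.q, (int, np.integer)) and self.q >= 1):
            raise ValueError("polynomial degree q must be a positive integer")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")


def kernel_matrix(X: np.ndarray, Y: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Gram matrix K[i, j] = K(X[i], Y[j])."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("feature dimensions differ")
    dots = X @ Y.T
    if spec.kind == "linear":
        return dots
    if spec.kind == "polynomial":
        return (dots + 1.0) ** spec.q
    sq = (X * X).sum(axis=1)[:, None] + (Y * Y).sum(axis=1)[None, :] - 2.0 * dots
    return np.exp(-np.maximum(sq, 0.0) / (2.0 * spec.sigma2))


def kernel_value(x: np.ndarray, y: np.ndarray, spec: KernelSpec) -> float:
    """Kernel evaluated on a single pair of feature vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("feature vectors must have equal length")
    return float(kernel_matrix(x[None, :], y[None, :], spec)[0, 0])


def dual_objective(alpha: np.ndarray, K: np.ndarray, s: np.ndarray) -> float:
    """Soft-margin dual objective sum(alpha) - 0.5 a^T (ss^T * K) a."""
    q = (s[:, None] * s[None, :]) * K
    return float(alpha.sum() - 0.5 * alpha @ q @ alpha)


def _smo(K: np.ndarray, s: np.ndarray, C: float, tol: float,
         max_iter: int) -> tuple[np.ndarray, float, float]:
    """Deterministic most-violating-pair SMO.

    Minimizes 0.5 a^T Q a - 1^T a with Q = (s s^T) * K subject to
    0 <= a <= C, s^T a = 0.  Returns (alpha, bias, final KKT gap).
    """
    n = K.shape[0]
    alpha = np.zeros(n)
    grad = -np.ones(n)  # gradient of the dual objective at alpha = 0
    gap = np.inf
    for _ in range(max_iter):
        viol = -s * grad
        up = ((s > 0) & (alpha < C - 1e-12)) | ((s < 0) & (alpha > 1e-12))
        low = ((s < 0) & (alpha < C - 1e-12)) | ((s > 0) & (alpha > 1e-12))
        if not up.any() or not low.any():
            gap = 0.0
            break
        i = int(np.flatnonzero(up)[np.argmax(viol[up])])
        j = int(np.flatnonzero(low)[np.argmin(viol[low])])
        gap = viol[i] - viol[j]
        if gap <= tol:
            break
        quad = max(K[i, i] + K[j, j] - 2.0 * K[i, j], 1e-12)
        delta = gap / quad
        # feasible step sizes along (d_i, d_j) = (s_i, -s_j)
        delta = min(delta,
                    (C - alpha[i]) if s[i] > 0 else alpha[i],
                    alpha[j] if s[j] > 0 else (C - alpha[j]))
        alpha[i] += s[i] * delta
        alpha[j] -= s[j] * delta
        grad += delta * (K[:, i] - K[:, j]) * s
    # bias from free support vectors, else the midpoint of the violation band
    viol = -s * grad
    free = (alpha > 1e-8) & (alpha < C - 1e-8)
    if free.any():
        b = float(viol[free].mean())
    else:
        up = ((s > 0) & (alpha < C - 1e-12)) | ((s < 0) & (alpha > 1e-12))
        low = ((s < 0) & (alpha < C - 1e-12)) | ((s > 0) & (alpha > 1e-12))
        hi = viol[up].max() if up.any() else viol[low].min()
        lo = viol[low].min() if low.any() else hi
        b = float(0.5 * (hi + lo))
    return alpha, b, float(max(gap, 0.0))


def _fit_platt(decision: np.ndarray, y01: np.ndarray,
               max_iter: int = 100) -> tuple[float, float]:
    """Platt sigmoid parameters (A, B) for P(y=1|f) = 1 / (1 + exp(A f + B)).

    Newton's method with backtracking on the regularized targets
    (Lin, Lin & Weng's numerically stable formulation).  Deterministic.
    """
    f = np.asarray(decision, dtype=float)
    n_pos = int((y01 == 1).sum())
    n_neg = int((y01 == 0).sum())
    t = np.where(y01 == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))
    a, b = 0.0, np.log((n_neg + 1.0) / (n_pos + 1.0))
    sigma_reg, min_step = 1e-12, 1e-10

    def objective(a_, b_):
        z = a_ * f + b_
        # cross-entropy with soft targets, computed stably on each side of 0
        val = np.where(z >= 0, t * z + np.log1p(np.exp(-np.abs(z))),
                       (t - 1.0) * z + np.log1p(np.exp(-np.abs(z))))
        return float(val.sum())

    err = objective(a, b)
    for _ in range(max_iter):
        z = a * f + b
        p = np.where(z >= 0, np.exp(-z) / (1.0 + np.exp(-z)),
                     1.0 / (1.0 + np.exp(z)))
        q = 1.0 - p  # q = 1/(1+exp(-z))
        d1 = t - p
        d2 = p * q
        g1 = float((f * d1).sum())
        g2 = float(d1.sum())
        if abs(g1) < 1e-5 and abs(g2) < 1e-5:
            break
        h11 = float((f * f * d2).sum()) + sigma_reg
        h22 = float(d2.sum()) + sigma_reg
        h21 = float((f * d2).sum())
        det = h11 * h22 - h21 * h21
        da = -(h22 * g1 - h21 * g2) / det
        db = -(-h21 * g1 + h11 * g2) / det
        gd = g1 * da + g2 * db
        step = 1.0
        while step >= min_step:
            new_err = objective(a + step * da, b + step * db)
            if new_err < err + 1e-4 * step * gd:
                a, b = a + step * da, b + step * db
                err = new_err
                break
            step *= 0.5
        else:
            break
    return a, b


class KernelSVC(ClassifierMixin, BaseEstimator):
    """Binary soft-margin SVM with calibrated probability-like scores.

    Parameters
    ----------
    kernel : {"linear", "polynomial", "gaussian"}
    q : int
        Polynomial degree (polynomial kernel only).
    sigma2 : float
        Gaussian width sigma^2.
    C : float
        Soft-margin box constraint.
    tol : float
        KKT violation tolerance of the dual solver.
    standardize : bool
        Standardize features to train mean/SD before the kernel.

    Fitted attributes include ``support_vectors_``, ``dual_coef_``
    (alpha_i * s_i over support vectors), ``intercept_``, the Platt
    parameters ``platt_a_``/``platt_b_`` and ``kkt_gap_``.
    """

    def __init__(self, kernel: str = "linear", q: int = 3, sigma2: float = 0.1,
                 C: float = 1.0, tol: float = 1e-3, max_iter: int = 200_000,
                 standardize: bool = True):
        self.kernel = kernel
        self.q = q
        self.sigma2 = sigma2
        self.C = C
        self.tol = tol
        self.max_iter = max_iter
        self.standardize = standardize

    def _spec(self) -> KernelSpec:
        return KernelSpec(self.kernel, self.q, self.sigma2)

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("KernelSVC is a binary classifier; need exactly "
                             f"2 classes, got {self.classes_.size}")
        y01 = (y == self.classes_[1]).astype(int)
        s = 2.0 * y01 - 1.0
        spec = self._spec()

        if self.standardize:
            self.mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.scale_ = np.where(sd > 0, sd, 1.0)
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        Xs = (X - self.mean_) / self.scale_

        K = kernel_matrix(Xs, Xs, spec)
        alpha, b, gap = _smo(K, s, self.C, self.tol, self.max_iter)
        self.kkt_gap_ = gap
        self.alpha_ = alpha
        sv = alpha > 1e-10
        self.support_ = np.flatnonzero(sv)
        self.support_vectors_ = Xs[sv]
        self.dual_coef_ = (alpha * s)[sv]
        self.intercept_ = b
        self.n_features_in_ = X.shape[1]

        decision = K @ (alpha * s) + b
        self.platt_a_, self.platt_b_ = _fit_platt(decision, y01)
        self.fit_decision_ = decision
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "dual_coef_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features, got {X.shape[1]}")
        Xs = (X - self.mean_) / self.scale_
        K = kernel_matrix(Xs, self.support_vectors_, self._spec())
        return K @ self.dual_coef_ + self.intercept_

    def predict_proba(self, X) -> np.ndarray:
        """Columns ordered as ``classes_``; column 1 is the score C in (0, 1)."""
        f = self.decision_function(X)
        z = self.platt_a_ * f + self.platt_b_
        p1 = np.where(z >= 0, np.exp(-z) / (1.0 + np.exp(-z)),
                      1.0 / (1.0 + np.exp(z)))
        return np.column_stack([1.0 - p1, p1])

    def score_samples(self, X) -> np.ndarray:
        """The calibrated score C in (0, 1) for the positive class."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        """Class 1 iff the calibrated score is >= 0.5."""
        scores = self.score_samples(X)
        return np.where(scores >= 0.5, self.classes_[1], self.classes_[0])

    def to_json(self) -> str:
        check_is_fitted(self, "dual_coef_")
        return json.dumps({
            "kernel": {"kind": self.kernel, "q": self.q, "sigma2": self.sigma2},
            "C": self.C,
            "support_vectors": self.support_vectors_.tolist(),
            "dual_coef": self.dual_coef_.tolist(),
            "intercept": self.intercept_,
            "platt": [self.platt_a_, self.platt_b_],
            "standardization": {"mean": self.mean_.tolist(),
                                "scale": self.scale_.tolist()},
            "classes": self.classes_.tolist(),
        })

    @classmethod
    def from_json(cls, payload: str) -> "KernelSVC":
        d = json.loads(payload)
        est = cls(kernel=d["kernel"]["kind"], q=d["kernel"]["q"],
                  sigma2=d["kernel"]["sigma2"], C=d["C"])
        est.support_vectors_ = np.asarray(d["support_vectors"], dtype=float)
        est.dual_coef_ = np.asarray(d["dual_coef"], dtype=float)
        est.intercept_ = float(d["intercept"])
        est.platt_a_, est.platt_b_ = d["platt"]
        est.mean_ = np.asarray(d["standardization"]["mean"], dtype=float)
        est.scale_ = np.asarray(d["standardization"]["scale"], dtype=float)
        est.classes_ = np.asarray(d["classes"])
        est.n_features_in_ = est.support_vectors_.shape[1]
        return est
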