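"""Kernel SVM: kernel identities, dual solver optimality, calibration."""

import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.svm import SVC

from pneumotex.svm import (KernelSpec, KernelSVC, dual_objective,
                           kernel_matrix, kernel_value)


def qp_oracle(K, s, C):
    """Brute-force dual maximization via an independent constrained solver."""
    n = len(s)
    Q = (s[:, None] * s[None, :]) * K
    res = minimize(lambda a: -(a.sum() - 0.5 * a @ Q @ a),
                   np.full(n, min(C / 2, 0.5)),
                   jac=lambda a: -(1 - Q @ a),
                   bounds=[(0, C)] * n,
                   constraints={"type": "eq", "fun": lambda a: a @ s,
                                "jac": lambda a: s},
                   method="SLSQP", options={"maxiter": 1000, "ftol": 1e-14})
    return -res.fun


class TestKernels:
    def test_printed_parameter_values(self):
        assert kernel_value([1, 2], [3, 4], KernelSpec("linear")) == 11.0
        assert kernel_value([1, 0], [1, 0], KernelSpec("polynomial", q=3)) == 8.0
        x = np.array([0.0, 0.0])
        y = np.array([np.sqrt(0.2), 0.0])  # ||x-y||^2 = 0.2
        assert kernel_value(x, x, KernelSpec("gaussian", sigma2=0.1)) == 1.0
        assert kernel_value(x, y, KernelSpec("gaussian", sigma2=0.1)) \
            == pytest.approx(np.exp(-1), rel=1e-12)

    def test_length_mismatch_and_bad_spec(self):
        with pytest.raises(ValueError):
            kernel_value([1, 2], [1, 2, 3], KernelSpec("linear"))
        with pytest.raises(ValueError):
            KernelSpec("gaussian", sigma2=0.0)
        with pytest.raises(ValueError):
            KernelSpec("polynomial", q=0)

    @pytest.mark.parametrize("kind", ["linear", "polynomial", "gaussian"])
    def test_gram_symmetric_and_psd(self, kind, rng):
        X = rng.normal(size=(15, 4))
        K = kernel_matrix(X, X, KernelSpec(kind))
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        assert np.linalg.eigvalsh(K).min() >= -1e-8
        if kind == "gaussian":
            np.testing.assert_allclose(np.diag(K), 1.0)


class TestTraining:
    def test_symmetric_pair_boundary_at_midpoint(self):
        model = KernelSVC(kernel="linear", C=10).fit(
            np.array([[-1.0], [1.0]]), np.array([0, 1]))
        assert model.decision_function([[0.0]])[0] == pytest.approx(0.0, abs=1e-9)
        assert model.predict([[0.5]])[0] == 1
        assert model.predict([[-0.5]])[0] == 0

    @pytest.mark.parametrize("kind", ["linear", "gaussian"])
    @pytest.mark.parametrize("trial", range(3))
    def test_dual_matches_brute_force_qp(self, kind, trial):
        rng = np.random.default_rng(10 * trial + 1)
        X = rng.normal(size=(6, 2))
        y = np.array([0, 0, 0, 1, 1, 1])
        s = 2.0 * y - 1
        spec = KernelSpec(kind)
        K = kernel_matrix(X, X, spec)
        model = KernelSVC(kernel=kind, C=1.0, tol=1e-6,
                          standardize=False).fit(X, y)
        assert dual_objective(model.alpha_, K, s) \
            == pytest.approx(qp_oracle(K, s, 1.0), abs=1e-4)

    def test_xor_separability(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([0, 0, 1, 1])
        linear = KernelSVC(kernel="linear", C=10).fit(X, y)
        gaussian = KernelSVC(kernel="gaussian", sigma2=0.1, C=10).fit(X, y)
        assert (linear.predict(X) == y).mean() <= 0.75
        assert (gaussian.predict(X) == y).mean() == 1.0

    def test_kkt_residual_within_tolerance(self, rng):
        X = rng.normal(size=(40, 3))
        y = (X[:, 0] + rng.normal(scale=0.8, size=40) > 0).astype(int)
        model = KernelSVC(kernel="gaussian", C=1.0).fit(X, y)
        assert model.kkt_gap_ <= model.tol

    def test_separable_data_with_large_c_has_zero_training_errors(self, rng):
        X = np.vstack([rng.normal(-3, 0.5, (15, 2)), rng.normal(3, 0.5, (15, 2))])
        y = np.repeat([0, 1], 15)
        model = KernelSVC(kernel="linear", C=100.0).fit(X, y)
        assert (model.predict(X) == y).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            KernelSVC().fit(np.zeros((4, 2)), np.zeros(4))

    def test_agrees_with_sklearn_on_linear_problem(self, rng):
        X = rng.normal(size=(30, 3))
        y = (X[:, 0] + 0.5 * X[:, 1] > 0).astype(int)
        mine = KernelSVC(kernel="linear", C=1.0, standardize=False).fit(X, y)
        ref = SVC(kernel="linear", C=1.0).fit(X, y)
        np.testing.assert_allclose(mine.decision_function(X),
                                   ref.decision_function(X), atol=5e-3)


class TestPrediction:
    def test_scores_in_unit_interval_and_monotone_in_decision(self, rng):
        X = rng.normal(size=(30, 2))
        y = (X[:, 0] > 0).astype(int)
        model = KernelSVC(kernel="linear", C=1.0).fit(X, y)
        Xt = rng.normal(size=(50, 2))
        f = model.decision_function(Xt)
        c = model.score_samples(Xt)
        assert np.all((c >= 0) & (c <= 1))
        order = np.argsort(f)
        assert np.all(np.diff(c[order]) > 0)  # strictly increasing calibration

    def test_prediction_follows_half_threshold_rule(self, rng):
        model = KernelSVC(kernel="linear", C=10).fit(
            np.array([[-1.0], [1.0]]), np.array([0, 1]))
        X = np.concatenate([[0.0], rng.normal(size=20)])[:, None]
        scores = model.score_samples(X)
        assert scores[0] == pytest.approx(0.5, abs=1e-9)  # midpoint decision
        np.testing.assert_array_equal(model.predict(X),
                                      np.where(scores >= 0.5, 1, 0))

    def test_dimension_mismatch_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        model = KernelSVC().fit(X, (X[:, 0] > 0).astype(int))
        with pytest.raises(ValueError):
            model.predict(rng.normal(size=(2, 4)))

    def test_json_roundtrip_preserves_predictions(self, rng):
        X = rng.normal(size=(20, 2))
        y = (X.sum(axis=1) > 0).astype(int)
        model = KernelSVC(kernel="polynomial", q=3, C=2.0).fit(X, y)
        clone = KernelSVC.from_json(model.to_json())
        np.testing.assert_allclose(clone.score_samples(X), model.score_samples(X),
                                   rtol=1e-12)
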