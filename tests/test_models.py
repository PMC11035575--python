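"""Closed-form ridge core and the model-comparison harness."""

import numpy as np
import pandas as pd
import pytest

from nirglucose.errors import ConfigurationError
from nirglucose.models import (
    ROSTER_NAMES,
    RidgeRegression,
    RidgeSpec,
    SplitConfig,
    fit_ridge,
    run_comparison,
)


def ridge_objective_gd(X, y, lam, n_iter=200_000):
    """Independent minimizer of the penalized least-squares objective
    sum (y - Xb)^2 + lam * ||b||^2 by plain gradient descent."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    b = np.zeros(X.shape[1])
    step = 1.0 / (2 * (np.linalg.eigvalsh(X.T @ X).max() + lam))
    for _ in range(n_iter):
        grad = 2 * (X.T @ (X @ b - y)) + 2 * lam * b
        b_new = b - step * grad
        if np.max(np.abs(b_new - b)) < 1e-14:
            return b_new
        b = b_new
    return b


class TestRidgeClosedForm:
    def test_two_by_two_identity_by_hand(self):
        # (I + I)^-1 y = y / 2
        model = RidgeRegression(RidgeSpec(lam=1.0, standardize=False,
                                          fit_intercept=False))
        model.fit(np.eye(2), np.array([1.0, 1.0]))
        assert np.allclose(model.coef_, [0.5, 0.5])

    def test_lambda_zero_equals_ols_pseudoinverse(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 5))
        y = rng.normal(size=40)
        model = RidgeRegression(RidgeSpec(lam=0.0, standardize=False,
                                          fit_intercept=False)).fit(X, y)
        assert np.allclose(model.coef_, np.linalg.pinv(X) @ y, atol=1e-10)

    def test_large_lambda_shrinks_to_zero(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        free = RidgeRegression(RidgeSpec(lam=0.0, standardize=False,
                                         fit_intercept=False)).fit(X, y)
        shrunk = RidgeRegression(RidgeSpec(lam=1e6, standardize=False,
                                           fit_intercept=False)).fit(X, y)
        assert np.linalg.norm(shrunk.coef_) < 1e-3 * np.linalg.norm(free.coef_)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ConfigurationError):
            RidgeSpec(lam=-0.1)

    def test_singular_system_at_lambda_zero_advises(self):
        X = np.ones((10, 2))  # duplicated column
        y = np.arange(10.0)
        with pytest.raises(np.linalg.LinAlgError, match="lam > 0"):
            RidgeRegression(RidgeSpec(lam=0.0, standardize=False,
                                      fit_intercept=False)).fit(X, y)

    def test_matches_gradient_descent_oracle(self):
        rng = np.random.default_rng(3)
        for lam in (0.1, 1.0, 10.0):
            X = rng.normal(size=(25, 4))
            y = rng.normal(size=25)
            closed = RidgeRegression(
                RidgeSpec(lam=lam, standardize=False, fit_intercept=False)
            ).fit(X, y)
            assert np.allclose(closed.coef_, ridge_objective_gd(X, y, lam),
                               atol=1e-6)

    def test_coefficient_norm_non_increasing_in_lambda(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 6))
        y = rng.normal(size=50)
        norms = [
            np.linalg.norm(
                RidgeRegression(RidgeSpec(lam=lam, standardize=False,
                                          fit_intercept=False)).fit(X, y).coef_
            )
            for lam in 10.0 ** np.arange(-3, 4)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(norms, norms[1:]))

    def test_parameter_recovery_within_three_se(self):
        rng = np.random.default_rng(5)
        n, p, sigma = 400, 4, 0.5
        X = rng.normal(size=(n, p))
        beta = np.array([1.5, -2.0, 0.7, 3.0])
        y = X @ beta + rng.normal(0, sigma, size=n)
        fit = RidgeRegression(RidgeSpec(lam=1e-8, standardize=False,
                                        fit_intercept=False)).fit(X, y)
        se = sigma * np.sqrt(np.diag(np.linalg.inv(X.T @ X)))
        assert np.all(np.abs(fit.coef_ - beta) <= 3 * se)

    def test_predict_shape_checks_and_intercept(self):
        X = np.array([[1.0], [2.0], [3.0]])
        y = np.array([2.0, 4.0, 6.0])
        fit = fit_ridge(X, y, RidgeSpec(lam=1e-10))
        assert np.allclose(fit.predict(X), y, atol=1e-4)
        with pytest.raises(ConfigurationError, match="mismatch"):
            fit.predict(np.ones((2, 3)))

    def test_zero_coefficient_fit_predicts_intercept(self):
        X = np.ones((5, 1)) * 2.0  # constant column carries no signal
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        fit = fit_ridge(X, y)
        assert np.allclose(fit.predict(X), y.mean())

    def test_hand_computed_two_point_prediction(self):
        model = RidgeRegression(RidgeSpec(lam=1.0, standardize=False,
                                          fit_intercept=False))
        model.fit(np.eye(2), np.array([1.0, 1.0]))
        assert np.allclose(model.predict(np.array([[2.0, 4.0]])), [3.0])


@pytest.fixture(scope="module")
def linear_branches():
    rng = np.random.default_rng(10)
    X = rng.normal(size=(150, 3))
    beta = np.array([2.0, -1.0, 0.5])
    return {
        "clean": (X, X @ beta + 5.0),
        "noisy": (X, X @ beta + 5.0 + rng.normal(0, 2.0, size=150)),
    }


class TestComparisonHarness:
    def test_ridge_on_realizable_target(self, linear_branches):
        report = run_comparison(linear_branches, models=["RR"])
        r2 = report.table.set_index("branch")["r2_score"]
        assert r2["clean"] > 0.99

    def test_deterministic_under_fixed_seed(self, linear_branches):
        kwargs = dict(models=["RR", "LR", "DT"], split=SplitConfig(seed=7))
        t1 = run_comparison(linear_branches, **kwargs).table
        t2 = run_comparison(linear_branches, **kwargs).table
        pd.testing.assert_frame_equal(t1, t2)

    def test_full_roster_cardinality(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(60, 3))
        y = X @ np.array([1.0, 2.0, -1.0]) + rng.normal(0, 0.1, size=60)
        branches = {b: (X, y) for b in ("raw", "normalized", "framework")}
        report = run_comparison(branches)
        assert len(report.table) == 36  # 12 models x 3 branches
        assert set(report.table["model"]) == set(ROSTER_NAMES)
        assert report.table.groupby("branch")["best"].sum().eq(1).all()

    def test_unknown_roster_entry_lists_valid_names(self, linear_branches):
        with pytest.raises(ConfigurationError, match="RR"):
            run_comparison(linear_branches, models=["SVM"])

    def test_best_flag_maximizes_r2(self, linear_branches):
        report = run_comparison(linear_branches, models=["RR", "DT", "k-NN"])
        for branch in linear_branches:
            sub = report.table[report.table["branch"] == branch]
            assert sub.loc[sub["best"], "r2_score"].iloc[0] == sub["r2_score"].max()
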