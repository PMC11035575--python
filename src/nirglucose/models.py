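"""Ridge regression core and the model-comparison harness.

Ridge minimizes the penalized least-squares objective

    sum_i (y_i - sum_k x_ik b_k)^2 + lambda * sum_k b_k^2

and is solved here in closed form, ``b = (X'X + lambda I)^-1 X'y``, on
z-scored features with an unpenalized intercept (the penalty is
scale-sensitive, so standardization is the default). The eleven comparator
regressors delegate to scikit-learn; they are comparators, not the
contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostRegressor, BaggingRegressor, RandomForestRegressor
from sklearn.linear_model import LassoCV, LinearRegression
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.tree import DecisionTreeRegressor

from .errors import ConfigurationError
from .evaluate import compute_metrics

__all__ = [
    "RidgeSpec",
    "RidgeRegression",
    "fit_ridge",
    "SplitConfig",
    "FitResult",
    "ComparisonReport",
    "ROSTER_NAMES",
    "build_roster",
    "run_comparison",
]


@dataclass(frozen=True)
class RidgeSpec:
    """Shrinkage weight and fitting options of the ridge core."""

    lam: float = 1.0
    standardize: bool = True
    fit_intercept: bool = True

    def __post_init__(self):
        if self.lam < 0:
            raise ConfigurationError(f"shrinkage lambda must be >= 0, got {self.lam}")


class RidgeRegression:
    """Closed-form ridge with optional feature standardization.

    At ``lam=0`` this reduces to ordinary least squares; a singular normal
    system at ``lam=0`` raises with advice to use a positive shrinkage.
    """

    def __init__(self, spec: RidgeSpec | None = None, **kwargs):
        self.spec = spec or RidgeSpec(**kwargs)
        self.coef_ = None
        self.intercept_ = 0.0
        self._mu = None
        self._sigma = None

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ConfigurationError("X must be a 2-D feature matrix")
        if X.shape[0] != y.shape[0]:
            raise ConfigurationError(
                f"row mismatch: X has {X.shape[0]} rows, y has {y.shape[0]}"
            )
        spec = self.spec
        if spec.standardize:
            self._mu = X.mean(axis=0)
            sigma = X.std(axis=0)
            sigma[sigma == 0] = 1.0  # constant columns carry no signal
            self._sigma = sigma
            Z = (X - self._mu) / self._sigma
        else:
            self._mu = np.zeros(X.shape[1])
            self._sigma = np.ones(X.shape[1])
            Z = X
        if spec.fit_intercept:
            y_off = y.mean()
            yc = y - y_off
        else:
            y_off = 0.0
            yc = y
        gram = Z.T @ Z + spec.lam * np.eye(Z.shape[1])
        try:
            self.coef_ = np.linalg.solve(gram, Z.T @ yc)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "normal equations are singular at lambda=0; "
                "use a positive shrinkage (lam > 0)"
            ) from None
        if spec.lam == 0 and np.linalg.matrix_rank(gram) < gram.shape[0]:
            raise np.linalg.LinAlgError(
                "normal equations are singular at lambda=0; "
                "use a positive shrinkage (lam > 0)"
            )
        self.intercept_ = y_off
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        if self.coef_ is None:
            raise ConfigurationError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ConfigurationError(
                f"feature count mismatch: fitted with {self.n_features_in_} "
                f"columns, got {X.shape[1] if X.ndim == 2 else 'non-2D'}"
            )
        Z = (X - self._mu) / self._sigma
        return Z @ self.coef_ + self.intercept_

    def get_params(self, deep=True):  # sklearn-style cloning support
        return {"spec": self.spec}

    def set_params(self, **params):
        if "spec" in params:
            self.spec = params["spec"]
        return self

    def to_dict(self) -> dict:
        """JSON-serializable fit state (name, coefficients, scaler, lambda)."""
        return {
            "model_name": "RR",
            "lam": self.spec.lam,
            "coefficients": None if self.coef_ is None else self.coef_.tolist(),
            "intercept": self.intercept_,
            "scaler_mean": None if self._mu is None else np.asarray(self._mu).tolist(),
            "scaler_scale": None if self._sigma is None else np.asarray(self._sigma).tolist(),
        }


def fit_ridge(X, y, spec: RidgeSpec | None = None) -> RidgeRegression:
    """Fit the closed-form ridge core; returns the fitted model."""
    return RidgeRegression(spec or RidgeSpec()).fit(X, y)


@dataclass(frozen=True)
class SplitConfig:
    """Shuffled train/test split; the study reports no protocol, so 80/20
    with a fixed seed is the default."""

    test_size: float = 0.2
    seed: int = 42

    def __post_init__(self):
        if not 0 < self.test_size < 1:
            raise ConfigurationError("test_size must be in (0, 1)")


@dataclass
class FitResult:
    """One fitted model's held-out predictions and split metadata."""

    model_name: str
    predictions: np.ndarray
    y_test: np.ndarray
    split: SplitConfig
    coefficients: np.ndarray | None = None


ROSTER_NAMES = (
    "LR", "PR", "Lasso CV", "RF", "RR", "k-NN", "k-NN bagging",
    "k-NN boosting", "DT", "DT bagging", "DT boosting", "NN",
)


def build_roster(seed: int = 42, ridge_spec: RidgeSpec | None = None,
                 poly_degree: int = 2) -> dict:
    """The twelve-model roster; every entry exposes fit(X, y)/predict(X).

    Ridge ("RR") is the in-repo closed form; the rest are pinned
    scikit-learn comparators with documented defaults.
    """
    knn = lambda: KNeighborsRegressor(n_neighbors=5)
    dt = lambda: DecisionTreeRegressor(random_state=seed)
    return {
        "LR": LinearRegression(),
        "PR": make_pipeline(
            PolynomialFeatures(degree=poly_degree, include_bias=False),
            LinearRegression(),
        ),
        "Lasso CV": make_pipeline(
            StandardScaler(), LassoCV(cv=5, random_state=seed, max_iter=50000)
        ),
        "RF": RandomForestRegressor(n_estimators=100, random_state=seed),
        "RR": RidgeRegression(ridge_spec or RidgeSpec()),
        "k-NN": knn(),
        "k-NN bagging": BaggingRegressor(knn(), n_estimators=10, random_state=seed),
        "k-NN boosting": AdaBoostRegressor(knn(), n_estimators=10, random_state=seed),
        "DT": dt(),
        "DT bagging": BaggingRegressor(dt(), n_estimators=10, random_state=seed),
        "DT boosting": AdaBoostRegressor(dt(), n_estimators=10, random_state=seed),
        "NN": make_pipeline(
            StandardScaler(),
            MLPRegressor(hidden_layer_sizes=(32,), max_iter=3000,
                         random_state=seed),
        ),
    }


@dataclass
class ComparisonReport:
    """Per-(branch, model) held-out metrics with the best row flagged.

    Best model per branch maximizes r2_score; ties break toward lower MAE.
    """

    table: pd.DataFrame
    fits: dict = field(default_factory=dict, repr=False)

    def best(self, branch: str) -> pd.Series:
        rows = self.table[self.table["branch"] == branch]
        if rows.empty:
            raise ConfigurationError(f"no rows for branch {branch!r}")
        return rows.loc[rows["best"]].iloc[0]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def run_comparison(
    branches: dict,
    roster: dict | None = None,
    models: list[str] | None = None,
    split: SplitConfig | None = None,
    ridge_spec: RidgeSpec | None = None,
) -> ComparisonReport:
    """Fit the roster on each dataset branch and report held-out metrics.

    ``branches`` maps a branch name to ``(X, y)`` (array-likes). One report
    row per (branch, model); deterministic under the fixed split seed.
    """
    split = split or SplitConfig()
    roster = roster if roster is not None else build_roster(
        seed=split.seed, ridge_spec=ridge_spec
    )
    if models is not None:
        unknown = [m for m in models if m not in roster]
        if unknown:
            raise ConfigurationError(
                f"unknown roster entries {unknown}; valid names: {sorted(roster)}"
            )
        roster = {name: roster[name] for name in models}

    rows, fits = [], {}
    for branch, (X, y) in branches.items():
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=split.test_size, random_state=split.seed, shuffle=True
        )
        for name, template in roster.items():
            model = _fresh(template)
            model.fit(X_tr, y_tr)
            pred = np.asarray(model.predict(X_te), dtype=float)
            m = compute_metrics(y_te, pred)
            coef = getattr(model, "coef_", None)
            fits[(branch, name)] = FitResult(
                model_name=name, predictions=pred, y_test=y_te, split=split,
                coefficients=None if coef is None else np.asarray(coef),
            )
            rows.append(
                {"branch": branch, "model": name, "MAE": m.mae,
                 "MSE": m.mse, "r2_score": m.r2}
            )
    table = pd.DataFrame(rows)
    table["best"] = False
    for branch in table["branch"].unique():
        sub = table[table["branch"] == branch]
        idx = sub.sort_values(["r2_score", "MAE"], ascending=[False, True]).index[0]
        table.loc[idx, "best"] = True
    return ComparisonReport(table=table, fits=fits)


def _fresh(template):
    """Fresh, unfitted copy of a roster entry."""
    if isinstance(template, RidgeRegression):
        return RidgeRegression(template.spec)
    from sklearn.base import clone

    return clone(template)
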