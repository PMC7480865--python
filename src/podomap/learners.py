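"""The six base suitability learners behind one fit/predict contract.

GLM    weighted logistic regression (unpenalised).
GAM    logistic model on a fixed cubic B-spline basis per covariate; the
       smoothness is set by the number of knots (hyperparameter ``n_knots``).
GBM    gradient-boosted trees, learning rate 0.005 and interaction depth 5 —
       slow shrinkage with up to five-way interactions.
ANN    a single-hidden-layer network trained by weighted cross-entropy
       (implemented here directly so observation weights enter the loss).
MARS   piecewise-linear hinge basis at quantile knots with an L1-penalised
       logistic fit, a light-weight adaptive-spline surrogate.
RF     random forest.

Every learner accepts observation weights, predicts probabilities of
presence, and is deterministic given its ``rng_seed``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import SplineTransformer

from .survey import ModelFrame

logger = logging.getLogger("podomap")

ALGORITHMS = ("GLM", "GAM", "GBM", "ANN", "MARS", "RF")

# defaults for the tuned GBM; everything else uses library defaults sized for
# desk-scale data
DEFAULT_HYPERPARAMETERS: dict[str, dict[str, Any]] = {
    "GLM": {},
    "GAM": {"n_knots": 5, "degree": 3, "C": 1.0},
    "GBM": {"learning_rate": 0.005, "interaction_depth": 5, "n_estimators": 2500},
    "ANN": {"n_hidden": 8, "alpha": 1e-3, "max_iter": 500},
    "MARS": {"quantile_knots": (0.25, 0.5, 0.75), "C": 1.0},
    "RF": {"n_estimators": 500},
}


class LearnerError(ValueError):
    pass


@dataclass(frozen=True)
class LearnerSpec:
    algorithm: str
    hyperparameters: tuple = ()  # (key, value) pairs; kept hashable
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise LearnerError(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")

    def params(self) -> dict[str, Any]:
        p = dict(DEFAULT_HYPERPARAMETERS[self.algorithm])
        p.update(dict(self.hyperparameters))
        return p


@dataclass
class FittedLearner:
    spec: LearnerSpec
    covariate_names: list[str]
    _predict: Any = field(repr=False)

    def predict_prob(self, features: pd.DataFrame) -> np.ndarray:
        """Presence probabilities for a covariate table.

        Columns must match the training covariates by name and order; rows
        with missing covariates yield NaN.
        """
        if list(features.columns) != self.covariate_names:
            raise LearnerError(
                f"covariate mismatch: model trained on {self.covariate_names}, "
                f"got {list(features.columns)}"
            )
        X = features.to_numpy(dtype=float)
        ok = np.isfinite(X).all(axis=1)
        out = np.full(len(X), np.nan)
        if ok.any():
            p = self._predict(X[ok])
            out[ok] = np.clip(p, 0.0, 1.0)
        return out


def _check_frame(frame: ModelFrame) -> None:
    if len(np.unique(frame.labels)) < 2:
        raise LearnerError("training frame contains a single class")
    if np.any(frame.weights <= 0):
        raise LearnerError("observation weights must be positive")
    zero_var = [c for c in frame.covariate_names if frame.X[c].nunique() <= 1]
    if zero_var:
        logger.warning("zero-variance covariates retained: %s", zero_var)


def _sklearn_predictor(model, transform=None):
    def predict(X):
        Z = transform(X) if transform is not None else X
        return model.predict_proba(Z)[:, 1]

    return predict


def _fit_glm(X, y, w, params, seed):
    model = LogisticRegression(C=np.inf, max_iter=2000)
    model.fit(X, y, sample_weight=w)
    return _sklearn_predictor(model)


def _fit_gam(X, y, w, params, seed):
    splines = SplineTransformer(
        n_knots=params["n_knots"], degree=params["degree"], include_bias=False
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Z = splines.fit_transform(X)
        model = LogisticRegression(C=params["C"], max_iter=2000)
        model.fit(Z, y, sample_weight=w)
    return _sklearn_predictor(model, splines.transform)


def _fit_gbm(X, y, w, params, seed):
    model = GradientBoostingClassifier(
        learning_rate=params["learning_rate"],
        max_depth=params["interaction_depth"],
        n_estimators=params["n_estimators"],
        random_state=seed,
    )
    model.fit(X, y, sample_weight=w)
    return _sklearn_predictor(model)


def _fit_rf(X, y, w, params, seed):
    model = RandomForestClassifier(n_estimators=params["n_estimators"], random_state=seed)
    model.fit(X, y, sample_weight=w)
    return _sklearn_predictor(model)


def _hinge_basis(X, knots_per_col):
    cols = [X]
    for j, knots in enumerate(knots_per_col):
        for k in knots:
            cols.append(np.maximum(X[:, j] - k, 0.0)[:, None])
            cols.append(np.maximum(k - X[:, j], 0.0)[:, None])
    return np.hstack(cols)


def _fit_mars(X, y, w, params, seed):
    qs = np.asarray(params["quantile_knots"], dtype=float)
    knots_per_col = [np.unique(np.quantile(X[:, j], qs)) for j in range(X.shape[1])]
    Z = _hinge_basis(X, knots_per_col)
    model = LogisticRegression(
        l1_ratio=1.0, C=params["C"], solver="liblinear", max_iter=2000
    )
    model.fit(Z, y, sample_weight=w)
    return _sklearn_predictor(model, lambda X_: _hinge_basis(X_, knots_per_col))


def _fit_ann(X, y, w, params, seed):
    """Single-hidden-layer tanh network, weighted cross-entropy, L2 penalty.

    Trained by L-BFGS with analytic gradients; inputs are standardised with
    weighted moments so the penalty acts on a common scale.
    """
    n, d = X.shape
    h = params["n_hidden"]
    alpha = params["alpha"]
    wn = w / w.sum()
    mu = wn @ X
    sd = np.sqrt(wn @ (X - mu) ** 2)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    rng = np.random.default_rng(seed)
    n_par = d * h + h + h + 1
    theta0 = rng.normal(scale=0.5, size=n_par)

    def unpack(theta):
        W1 = theta[: d * h].reshape(d, h)
        b1 = theta[d * h : d * h + h]
        w2 = theta[d * h + h : d * h + 2 * h]
        b2 = theta[-1]
        return W1, b1, w2, b2

    def loss_grad(theta):
        W1, b1, w2, b2 = unpack(theta)
        A = np.tanh(Xs @ W1 + b1)
        z = A @ w2 + b2
        p = expit(z)
        eps = 1e-12
        ll = -(wn @ (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
        reg = alpha * (np.sum(W1**2) + np.sum(w2**2))
        dz = wn * (p - y)
        gw2 = A.T @ dz + 2 * alpha * w2
        gb2 = dz.sum()
        dA = np.outer(dz, w2) * (1 - A**2)
        gW1 = Xs.T @ dA + 2 * alpha * W1
        gb1 = dA.sum(axis=0)
        grad = np.concatenate([gW1.ravel(), gb1, gw2, [gb2]])
        return ll + reg, grad

    res = minimize(
        loss_grad, theta0, jac=True, method="L-BFGS-B",
        options={"maxiter": params["max_iter"]},
    )
    W1, b1, w2, b2 = unpack(res.x)

    def predict(X_):
        A = np.tanh(((X_ - mu) / sd) @ W1 + b1)
        return expit(A @ w2 + b2)

    return predict


_FITTERS = {
    "GLM": _fit_glm,
    "GAM": _fit_gam,
    "GBM": _fit_gbm,
    "ANN": _fit_ann,
    "MARS": _fit_mars,
    "RF": _fit_rf,
}


def fit_learner(spec: LearnerSpec, frame: ModelFrame) -> FittedLearner:
    """Fit one base learner on a weighted training frame."""
    _check_frame(frame)
    X = frame.X.to_numpy(dtype=float)
    y = frame.labels.astype(float)
    w = frame.weights
    predict = _FITTERS[spec.algorithm](X, y, w, spec.params(), spec.rng_seed)
    return FittedLearner(spec=spec, covariate_names=frame.covariate_names, _predict=predict)


def partial_dependence(
    model: FittedLearner, frame: ModelFrame, covariate: str, grid
) -> pd.DataFrame:
    """Marginal effect of one covariate: for each grid value v, the mean
    prediction over all training rows with that covariate set to v."""
    if covariate not in frame.covariate_names:
        raise LearnerError(f"covariate {covariate!r} not in frame")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise LearnerError("empty partial-dependence grid")
    means = []
    for v in grid:
        X = frame.X.copy()
        X[covariate] = v
        means.append(float(np.nanmean(model.predict_prob(X))))
    return pd.DataFrame({"value": grid, "mean_prediction": means})
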