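"""Ridge-penalized logistic regression with the 1-SE penalty rule.

The classifier used downstream of every feature selector. The penalty is
chosen within each training split by K-fold cross-validation of the binomial
deviance over a log-spaced grid, applying the 1-SE rule: the *largest*
penalty whose CV loss is within one standard error of the minimum (lambda.1se
in glmnet's terms) — a deliberately conservative choice for small cohorts.

Objective (intercept unpenalized, X assumed standardized):

    (1/n) * sum_i logloss_i + (lambda/2) * ||beta||^2

The whole penalty path is fit by Newton/IRLS batched across the grid, which
keeps the 100-lambda x 10-fold search effectively free at cohort scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from .exceptions import ConfigurationError, ContractError


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -35.0, 35.0)))


def ridge_logistic_path(X: np.ndarray, y: np.ndarray, lambdas: np.ndarray,
                        max_iter: int = 60, tol: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """Fit the ridge logistic path; returns (coefs [L,p], intercepts [L])."""
    n, p = X.shape
    Z = np.hstack([np.ones((n, 1)), X])
    L = len(lambdas)
    B = np.zeros((L, p + 1))
    ybar = float(np.mean(y))
    if not 0.0 < ybar < 1.0:
        raise ConfigurationError("training labels must contain both classes")
    B[:, 0] = np.log(ybar / (1.0 - ybar))
    pen_mask = np.zeros(p + 1)
    pen_mask[1:] = 1.0
    lam = np.asarray(lambdas, dtype=float)

    def penalized_loss(Bm):
        eta = Bm @ Z.T
        pr = _sigmoid(eta)
        pr = np.clip(pr, 1e-12, 1 - 1e-12)
        ll = -(y * np.log(pr) + (1 - y) * np.log(1 - pr)).mean(axis=1)
        return ll + 0.5 * lam * (Bm[:, 1:] ** 2).sum(axis=1)

    loss = penalized_loss(B)
    for _ in range(max_iter):
        eta = B @ Z.T  # (L, n)
        pr = _sigmoid(eta)
        w = pr * (1.0 - pr) + 1e-10
        grad = (y[None, :] - pr) @ Z / n - lam[:, None] * B * pen_mask
        H = np.einsum("ln,ni,nj->lij", w, Z, Z) / n
        H += lam[:, None, None] * np.eye(p + 1) * pen_mask[None, :, None] * pen_mask[None, None, :]
        H[:, 0, 0] += 0.0
        step = np.linalg.solve(H, grad[..., None])[..., 0]
        # per-lambda step halving until the penalized loss does not increase
        scale = np.ones(L)
        for _half in range(30):
            B_new = B + scale[:, None] * step
            loss_new = penalized_loss(B_new)
            worse = loss_new > loss + 1e-12
            if not worse.any():
                break
            scale[worse] *= 0.5
        B = B + scale[:, None] * step
        new_loss = penalized_loss(B)
        if np.max(np.abs(scale[:, None] * step)) < tol:
            loss = new_loss
            break
        loss = new_loss
    return B[:, 1:], B[:, 0]


def binomial_deviance(prob: np.ndarray, y: np.ndarray) -> float:
    """Mean binomial deviance, 2x the mean negative log-likelihood."""
    pr = np.clip(prob, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(pr) + (1 - y) * np.log(1 - pr)))


class RidgeLogistic1SE(ClassifierMixin, BaseEstimator):
    """Ridge logistic classifier with CV-based 1-SE penalty selection.

    Parameters
    ----------
    n_lambdas, lambda_min, lambda_max : penalty grid (log-spaced).
    cv : internal stratified folds for the deviance curve.
    random_state : fold shuffling seed.

    Fitted attributes: ``lambda_`` (chosen penalty), ``coef_``,
    ``intercept_``, ``cv_loss_``, ``cv_loss_se_``, ``lambdas_``.
    """

    def __init__(self, n_lambdas: int = 100, lambda_min: float = 1e-4,
                 lambda_max: float = 1e3, cv: int = 10, random_state: int | None = 0):
        self.n_lambdas = n_lambdas
        self.lambda_min = lambda_min
        self.lambda_max = lambda_max
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ConfigurationError(
                f"ridge classifier needs exactly two classes, got {len(self.classes_)}"
            )
        yb = (y == self.classes_[1]).astype(float)
        # grid ordered descending so the 1-SE pick is the first qualifying entry
        self.lambdas_ = np.geomspace(self.lambda_max, self.lambda_min, self.n_lambdas)

        n = len(yb)
        n_folds = min(self.cv, int(np.bincount(yb.astype(int)).min()))
        if n_folds < 2:
            raise ConfigurationError("too few samples per class for internal CV")
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=self.random_state)
        fold_losses = np.zeros((n_folds, self.n_lambdas))
        for f, (tr, te) in enumerate(skf.split(X, yb)):
            coefs, icepts = ridge_logistic_path(X[tr], yb[tr], self.lambdas_)
            prob = _sigmoid(coefs @ X[te].T + icepts[:, None])
            pr = np.clip(prob, 1e-12, 1 - 1e-12)
            fold_losses[f] = -2.0 * np.mean(
                yb[te] * np.log(pr) + (1 - yb[te]) * np.log(1 - pr), axis=1
            )
        self.cv_loss_ = fold_losses.mean(axis=0)
        self.cv_loss_se_ = fold_losses.std(axis=0, ddof=1) / np.sqrt(n_folds)
        self.lambda_ = choose_lambda_1se(self.lambdas_, self.cv_loss_, self.cv_loss_se_)

        coefs, icepts = ridge_logistic_path(X, yb, np.array([self.lambda_]))
        self.coef_ = coefs[0]
        self.intercept_ = float(icepts[0])
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ContractError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        p1 = _sigmoid(X @ self.coef_ + self.intercept_)
        p1 = np.clip(p1, 1e-12, 1 - 1e-12)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]


def choose_lambda_1se(lambdas: np.ndarray, cv_loss: np.ndarray, cv_se: np.ndarray) -> float:
    """Largest penalty whose CV loss is within one SE of the minimum."""
    order = np.argsort(lambdas)[::-1]  # descending
    lam_desc, loss_desc = lambdas[order], cv_loss[order]
    i_min = int(np.argmin(loss_desc))
    threshold = loss_desc[i_min] + cv_se[order][i_min]
    qualifying = np.flatnonzero(loss_desc <= threshold)
    return float(lam_desc[qualifying[0]])


@dataclass
class RidgeFit:
    """A fitted per-split ridge model plus its train-derived preprocessing."""

    feature_ids: list[str]
    imputation_values: pd.Series  # per-feature training median
    standardization_mean: pd.Series
    standardization_sd: pd.Series
    penalty: float
    coefficients: np.ndarray
    intercept: float
    estimator: RidgeLogistic1SE = field(repr=False, default=None)


def fit_ridge(
    x_train: np.ndarray,
    y_train: np.ndarray,
    internal_folds: int = 10,
    seed: int = 0,
    feature_ids: list[str] | None = None,
    imputation_values: pd.Series | None = None,
    standardization_mean: pd.Series | None = None,
    standardization_sd: pd.Series | None = None,
) -> RidgeFit:
    """Fit the 1-SE ridge classifier on a complete, standardized train matrix."""
    est = RidgeLogistic1SE(cv=internal_folds, random_state=seed).fit(x_train, y_train)
    p = x_train.shape[1]
    ids = feature_ids if feature_ids is not None else [f"x{i}" for i in range(p)]
    zero = pd.Series(np.zeros(p), index=ids)
    one = pd.Series(np.ones(p), index=ids)
    return RidgeFit(
        feature_ids=list(ids),
        imputation_values=zero if imputation_values is None else imputation_values,
        standardization_mean=zero if standardization_mean is None else standardization_mean,
        standardization_sd=one if standardization_sd is None else standardization_sd,
        penalty=est.lambda_,
        coefficients=est.coef_.copy(),
        intercept=est.intercept_,
        estimator=est,
    )


def apply_ridge(fit: RidgeFit, x_test: np.ndarray) -> np.ndarray:
    """Predicted probabilities of the second class; inputs must already be
    imputed/standardized with the fit's training parameters."""
    x = np.asarray(x_test, dtype=float)
    if x.shape[1] != len(fit.feature_ids):
        raise ContractError(
            f"expected {len(fit.feature_ids)} features, got {x.shape[1]}"
        )
    p1 = _sigmoid(x @ fit.coefficients + fit.intercept)
    return np.clip(p1, 1e-12, 1 - 1e-12)
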