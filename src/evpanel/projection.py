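"""PCA and PLS-DA on centered/scaled data, with VIP scores.

PLS-DA is fit by the classical NIPALS algorithm against a centered
class-indicator matrix (one column per class). Variable importance in
projection (VIP) summarizes each protein's contribution across components:

    VIP_j = sqrt( p * sum_a SSY_a * w_ja^2 / sum_a SSY_a )

with unit-norm x-weights ``w_a`` and per-component explained response sum of
squares ``SSY_a``; mean squared VIP equals 1 by construction.

Both decompositions fix component signs deterministically: each component is
flipped so that its largest-magnitude weight (loading for PCA) is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.model_selection import RepeatedStratifiedKFold

from .exceptions import ConfigurationError, ContractError, DataIntegrityError
from .matrix import ExpressionMatrix


@dataclass
class ProjectionModel:
    """Fitted projection summary (PCA or PLS-DA)."""

    kind: str  # "pca" | "plsda"
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # proteins x components (weights for plsda)
    variance_explained: np.ndarray  # per component, fraction of X variance
    n_components: int
    scaling_mean: pd.Series | None = None
    scaling_sd: pd.Series | None = None
    estimator: object | None = field(default=None, repr=False)


def _as_array(matrix) -> tuple[np.ndarray, pd.Index, pd.Index]:
    if isinstance(matrix, ExpressionMatrix):
        return (
            matrix.values.to_numpy(dtype=float),
            matrix.sample_ids,
            matrix.protein_ids,
        )
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float), matrix.index, matrix.columns
    x = np.asarray(matrix, dtype=float)
    return x, pd.RangeIndex(x.shape[0]), pd.RangeIndex(x.shape[1])


def _sign_fix(vectors: np.ndarray) -> np.ndarray:
    """Per column: +1 if the largest-|.| element is positive, else -1."""
    idx = np.abs(vectors).argmax(axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return signs


class PLSDiscriminant(ClassifierMixin, TransformerMixin, BaseEstimator):
    """NIPALS PLS-DA: partial least squares against class indicators.

    Parameters
    ----------
    n_components : int
        Number of latent variables to extract (capped by the data rank).
    scale : bool
        Unit-variance scale X columns (always centered).
    max_iter, tol : NIPALS inner-loop control.

    Fitted attributes use the proteins-in-columns convention:
    ``x_weights_`` (p x A, unit norm), ``x_loadings_`` (p x A),
    ``y_loadings_`` (C x A), ``x_scores_`` (n x A), ``ssy_explained_`` (A,),
    ``variance_explained_`` (A, fraction of X variance).
    """

    def __init__(self, n_components: int = 2, scale: bool = True,
                 max_iter: int = 500, tol: float = 1e-10):
        self.n_components = n_components
        self.scale = scale
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.n_components < 1:
            raise ConfigurationError(f"n_components must be >= 1, got {self.n_components}")
        if np.isnan(X).any():
            raise DataIntegrityError("PLS-DA requires complete (imputed) data")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ConfigurationError("PLS-DA needs at least two classes")
        n, p = X.shape
        Y = (y[:, None] == self.classes_[None, :]).astype(float)

        self.x_mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        self.x_std_ = sd if self.scale else np.ones(p)
        Xc = (X - self.x_mean_) / self.x_std_
        self.y_mean_ = Y.mean(axis=0)
        Yc = Y - self.y_mean_

        ssx_total = (Xc**2).sum()
        A = min(self.n_components, n - 1, p)
        W = np.zeros((p, A))
        P = np.zeros((p, A))
        Q = np.zeros((Y.shape[1], A))
        T = np.zeros((n, A))
        ssy = np.zeros(A)
        varx = np.zeros(A)
        Xd, Yd = Xc.copy(), Yc.copy()
        a_eff = 0
        for a in range(A):
            u = Yd[:, np.argmax((Yd**2).sum(axis=0))].copy()
            if (u**2).sum() < 1e-12:
                break
            t = np.zeros(n)
            for _ in range(self.max_iter):
                w = Xd.T @ u
                nw = np.linalg.norm(w)
                if nw < 1e-12:
                    break
                w /= nw
                t_new = Xd @ w
                q = Yd.T @ t_new / (t_new @ t_new)
                u = Yd @ q / (q @ q)
                if np.linalg.norm(t_new - t) < self.tol * max(1.0, np.linalg.norm(t_new)):
                    t = t_new
                    break
                t = t_new
            tt = t @ t
            if tt < 1e-12:
                break
            sign = _sign_fix(w[:, None])[0]
            w, t = sign * w, sign * t
            q = Yd.T @ t / tt
            pl = Xd.T @ t / tt
            Xd = Xd - np.outer(t, pl)
            Yd = Yd - np.outer(t, q)
            W[:, a], P[:, a], Q[:, a], T[:, a] = w, pl, q, t
            ssy[a] = tt * (q @ q)
            varx[a] = tt * (pl @ pl) / ssx_total if ssx_total > 0 else 0.0
            a_eff = a + 1
        if a_eff == 0:
            raise DataIntegrityError("PLS-DA found no usable component (degenerate data)")
        self.n_components_ = a_eff
        self.x_weights_ = W[:, :a_eff]
        self.x_loadings_ = P[:, :a_eff]
        self.y_loadings_ = Q[:, :a_eff]
        self.x_scores_ = T[:, :a_eff]
        self.ssy_explained_ = ssy[:a_eff]
        self.variance_explained_ = varx[:a_eff]
        # rotation for projecting new data: T = Xc @ R
        self.x_rotations_ = self.x_weights_ @ np.linalg.pinv(
            self.x_loadings_.T @ self.x_weights_
        )
        return self

    def transform(self, X, n_components: int | None = None):
        # P'W is triangular for NIPALS, so truncating the full rotation's
        # columns equals refitting the rotation with fewer components
        X = np.asarray(X, dtype=float)
        k = self.n_components_ if n_components is None else min(n_components, self.n_components_)
        Xc = (X - self.x_mean_) / self.x_std_
        return Xc @ self.x_rotations_[:, :k]

    def decision_function(self, X, n_components: int | None = None):
        T = self.transform(X, n_components)
        k = T.shape[1]
        return T @ self.y_loadings_[:, :k].T + self.y_mean_

    def predict(self, X, n_components: int | None = None):
        scores = self.decision_function(X, n_components)
        return self.classes_[np.argmax(scores, axis=1)]

    def vip(self) -> np.ndarray:
        """Variable importance in projection; mean squared VIP = 1."""
        w2 = self.x_weights_**2  # unit-norm columns
        ssy = self.ssy_explained_
        denom = ssy.sum()
        if denom <= 0:
            return np.ones(self.x_weights_.shape[0])
        p = self.x_weights_.shape[0]
        return np.sqrt(p * (w2 @ ssy) / denom)


def fit_plsda(
    matrix,
    class_labels,
    n_components: int = 2,
    scale: bool = True,
) -> ProjectionModel:
    """Fit PLS-DA on centered/scaled data and return a projection summary."""
    x, samples, proteins = _as_array(matrix)
    est = PLSDiscriminant(n_components=n_components, scale=scale).fit(x, np.asarray(class_labels))
    comps = [f"LV{i + 1}" for i in range(est.n_components_)]
    return ProjectionModel(
        kind="plsda",
        scores=pd.DataFrame(est.x_scores_, index=samples, columns=comps),
        loadings=pd.DataFrame(est.x_weights_, index=proteins, columns=comps),
        variance_explained=est.variance_explained_,
        n_components=est.n_components_,
        scaling_mean=pd.Series(est.x_mean_, index=proteins),
        scaling_sd=pd.Series(est.x_std_, index=proteins),
        estimator=est,
    )


def fit_pca(matrix, n_components: int = 2, scale: bool = True) -> ProjectionModel:
    """PCA of centered (optionally unit-scaled) NPX data.

    Components are ordered by decreasing explained variance; signs are fixed
    so each component's largest-magnitude loading is positive.
    """
    x, samples, proteins = _as_array(matrix)
    if np.isnan(x).any():
        raise DataIntegrityError("PCA requires complete (imputed) data")
    max_comp = min(x.shape[0] - 1, x.shape[1])
    if not 1 <= n_components <= max_comp:
        raise ConfigurationError(
            f"n_components must be in [1, {max_comp}], got {n_components}"
        )
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    xc = (x - mean) / sd if scale else x - mean
    est = PCA(n_components=n_components, svd_solver="full").fit(xc)
    signs = _sign_fix(est.components_.T)
    loadings = est.components_.T * signs
    scores = est.transform(xc) * signs
    comps = [f"PC{i + 1}" for i in range(n_components)]
    return ProjectionModel(
        kind="pca",
        scores=pd.DataFrame(scores, index=samples, columns=comps),
        loadings=pd.DataFrame(loadings, index=proteins, columns=comps),
        variance_explained=est.explained_variance_ratio_.copy(),
        n_components=n_components,
        scaling_mean=pd.Series(mean, index=proteins),
        scaling_sd=pd.Series(sd if scale else np.ones_like(sd), index=proteins),
        estimator=est,
    )


def vip(model: ProjectionModel) -> pd.Series:
    """VIP scores of a fitted PLS-DA projection (errors on PCA models)."""
    if model.kind != "plsda" or not isinstance(model.estimator, PLSDiscriminant):
        raise ContractError("VIP is defined only for PLS-DA models")
    return pd.Series(model.estimator.vip(), index=model.loadings.index, name="vip")


def choose_components_cv(
    matrix,
    labels,
    max_components: int = 5,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    scale: bool = True,
) -> int:
    """Component count minimizing repeated-CV balanced misclassification.

    Stratified ``folds``-fold CV repeated ``repeats`` times; within each
    training fold one PLS-DA model with the maximum component count is fit
    and truncated to score every candidate count, class assignment by maximum
    indicator score. Ties go to the smaller count.
    """
    x, _, _ = _as_array(matrix)
    y = np.asarray(labels)
    if max_components < 1:
        raise ConfigurationError(f"max_components must be >= 1, got {max_components}")
    classes, counts = np.unique(y, return_counts=True)
    if folds > counts.min():
        raise ConfigurationError(
            f"folds ({folds}) exceeds smallest class size ({counts.min()})"
        )
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    errors = np.zeros(max_components)
    counts_k = np.zeros(max_components)
    for train, test in cv.split(x, y):
        est = PLSDiscriminant(n_components=max_components, scale=scale).fit(x[train], y[train])
        t_full = est.transform(x[test])
        for k in range(1, max_components + 1):
            keff = min(k, est.n_components_)
            scores = t_full[:, :keff] @ est.y_loadings_[:, :keff].T + est.y_mean_
            pred = est.classes_[np.argmax(scores, axis=1)]
            # balanced misclassification over classes present in the fold
            errs = []
            for c in classes:
                m = y[test] == c
                if m.any():
                    errs.append(float(np.mean(pred[m] != c)))
            errors[k - 1] += float(np.mean(errs))
            counts_k[k - 1] += 1
    mean_err = errors / counts_k
    return int(np.argmin(np.round(mean_err, 12)) + 1)
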