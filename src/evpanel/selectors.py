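"""The three in-split feature selectors: Boruta-style shadow features,
elastic-net, and PLS-DA/VIP. Each returns its top five proteins.

All three are deterministic functions of (X, y, random_state). Ties in any
importance ranking break lexicographically on the feature name, so repeated
calls agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold

from ._fast import enet_logistic_path, rf_importances, rf_oob_permutation_z
from .exceptions import ConfigurationError, DataIntegrityError
from .projection import PLSDiscriminant, choose_components_cv
from .stats import empirical_auc

TOP_K = 5


@dataclass
class SelectorOutput:
    """One selector's ranked top features for one resampling split."""

    model: str  # "boruta" | "elastic_net" | "plsda"
    split_index: int
    selected: list[str]  # ordered, length <= 5
    importance: dict[str, float]
    diagnostics: dict = field(default_factory=dict)


def _rank_features(names: np.ndarray, importance: np.ndarray, candidates: np.ndarray) -> list[str]:
    """Candidates ordered by decreasing importance, ties lexicographic."""
    order = sorted(candidates, key=lambda i: (-importance[i], str(names[i])))
    return [str(names[i]) for i in order]


def _validate_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.isfinite(X).all():
        raise DataIntegrityError("feature matrix must be finite (impute first)")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ConfigurationError(f"selectors need exactly two classes, got {len(classes)}")
    yb = (y == classes[1]).astype(np.int64)
    return X, yb, classes


class BorutaSelector(BaseEstimator):
    """All-relevant selection by comparison with shuffled shadow features.

    Each iteration appends a column-permuted copy of the full matrix, fits a
    random forest and scores a "hit" for every real feature whose importance
    beats the best shadow. The default importance is the OOB permutation
    importance Z-score (mean OOB error increase over its standard error, the
    permutation-importance convention); ``importance="gini"`` switches to
    impurity importance, which is faster but markedly more liberal on
    chance-associated features at small n. After ``n_iter``
    iterations a two-sided binomial test per feature (level ``conf``,
    Bonferroni-corrected across features) classifies features as
    confirmed / tentative / rejected. Features are ranked by median
    importance; the selection takes confirmed features first and falls back
    to tentative ones when fewer than ``top_k`` are confirmed.
    """

    def __init__(self, n_iter: int = 500, conf: float = 0.01,
                 correction: str = "bonferroni", n_estimators: int = 500,
                 max_depth: int = 100, importance: str = "permutation_z",
                 top_k: int = TOP_K, random_state: int | None = 0):
        self.n_iter = n_iter
        self.conf = conf
        self.correction = correction
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.importance = importance
        self.top_k = top_k
        self.random_state = random_state

    def fit(self, X, y, feature_names=None):
        if self.n_iter < 1:
            raise ConfigurationError(f"n_iter must be >= 1, got {self.n_iter}")
        if self.correction != "bonferroni":
            raise ConfigurationError(f"unknown correction {self.correction!r}")
        if self.importance not in ("permutation_z", "gini"):
            raise ConfigurationError(f"unknown importance {self.importance!r}")
        X, yb, _ = _validate_xy(X, y)
        n, p = X.shape
        names = np.asarray(feature_names if feature_names is not None else
                           [f"x{i}" for i in range(p)])
        rng = np.random.default_rng(self.random_state)
        mtry = max(1, int(np.sqrt(2 * p)))
        hits = np.zeros(p, dtype=int)
        imp_history = np.empty((self.n_iter, p))
        for it in range(self.n_iter):
            shadow = rng.permuted(X, axis=0)
            xa = np.ascontiguousarray(np.hstack([X, shadow]))
            seed = int(rng.integers(0, 2**31 - 1))
            if self.importance == "permutation_z":
                imp = rf_oob_permutation_z(xa, yb, self.n_estimators, mtry,
                                           self.max_depth, seed)
            else:
                imp = rf_importances(xa, yb, self.n_estimators, mtry,
                                     self.max_depth, seed)
            shadow_max = imp[p:].max()
            hits += imp[:p] > shadow_max
            imp_history[it] = imp[:p]

        # two-sided binomial test of the hit count against chance (1/2)
        pv = np.minimum(
            1.0,
            2.0 * np.minimum(
                sps.binom.cdf(hits, self.n_iter, 0.5),
                sps.binom.sf(hits - 1, self.n_iter, 0.5),
            ),
        )
        threshold = self.conf / p  # Bonferroni across features
        half = self.n_iter / 2.0
        confirmed = np.flatnonzero((pv < threshold) & (hits > half))
        rejected = np.flatnonzero((pv < threshold) & (hits < half))
        tentative = np.setdiff1d(np.arange(p), np.union1d(confirmed, rejected))

        median_imp = np.median(imp_history, axis=0)
        selected = _rank_features(names, median_imp, confirmed)[: self.top_k]
        if len(selected) < self.top_k:
            fallback = _rank_features(names, median_imp, tentative)
            selected += fallback[: self.top_k - len(selected)]

        self.feature_names_ = names
        self.hits_ = hits
        self.p_values_ = pv
        self.importances_median_ = median_imp
        self.confirmed_ = [str(names[i]) for i in confirmed]
        self.tentative_ = [str(names[i]) for i in tentative]
        self.rejected_ = [str(names[i]) for i in rejected]
        self.selected_ = selected
        return self

    def output(self, split_index: int = 0) -> SelectorOutput:
        return SelectorOutput(
            model="boruta",
            split_index=split_index,
            selected=list(self.selected_),
            importance={str(n): float(v) for n, v in
                        zip(self.feature_names_, self.importances_median_)},
            diagnostics={
                "confirmed": self.confirmed_,
                "tentative": self.tentative_,
                "rejected": self.rejected_,
                "n_iter": self.n_iter,
                "n_estimators": self.n_estimators,
                "importance": self.importance,
            },
        )


class ElasticNetSelector(BaseEstimator):
    """Penalized logistic path (L1/L2 mix 0.5), penalty chosen by CV AUC.

    Fits a glmnet-style elastic-net logistic path, picks the penalty
    maximizing mean validation AUC over stratified internal folds (ties go
    to the stronger penalty), refits on the full data, keeps non-zero
    coefficients and returns the top five by absolute coefficient. The
    selection may legitimately be empty when the CV-optimal path point is
    fully sparse.
    """

    def __init__(self, l1_ratio: float = 0.5, n_lambdas: int = 30,
                 lambda_min_ratio: float = 1e-3, cv: int = 5,
                 top_k: int = TOP_K, random_state: int | None = 0):
        self.l1_ratio = l1_ratio
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.top_k = top_k
        self.random_state = random_state

    def fit(self, X, y, feature_names=None):
        X, yb, _ = _validate_xy(X, y)
        n, p = X.shape
        names = np.asarray(feature_names if feature_names is not None else
                           [f"x{i}" for i in range(p)])
        yf = yb.astype(float)
        lam_max = np.abs(X.T @ (yf - yf.mean())).max() / (n * max(self.l1_ratio, 1e-3))
        lam_max = max(lam_max, 1e-8)
        lambdas = np.geomspace(lam_max, lam_max * self.lambda_min_ratio, self.n_lambdas)

        n_folds = min(self.cv, int(np.bincount(yb).min()))
        if n_folds < 2:
            raise ConfigurationError("too few samples per class for internal CV")
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=self.random_state)
        aucs = np.zeros((n_folds, len(lambdas)))
        for f, (tr, te) in enumerate(skf.split(X, yb)):
            coefs, icepts = enet_logistic_path(
                np.ascontiguousarray(X[tr]), yf[tr], lambdas, self.l1_ratio, 50, 200, 1e-7
            )
            eta = coefs @ X[te].T + icepts[:, None]
            for li in range(len(lambdas)):
                if np.unique(eta[li]).size < 2:
                    aucs[f, li] = 0.5
                else:
                    aucs[f, li] = empirical_auc(yb[te], eta[li])
        mean_auc = aucs.mean(axis=0)
        best = int(np.argmax(np.round(mean_auc, 12)))  # first (largest lambda) on ties
        coefs, icepts = enet_logistic_path(
            np.ascontiguousarray(X), yf, lambdas, self.l1_ratio, 50, 200, 1e-7
        )
        coef = coefs[best]
        nonzero = np.flatnonzero(coef != 0.0)
        selected = _rank_features(names, np.abs(coef), nonzero)[: self.top_k]

        self.feature_names_ = names
        self.lambdas_ = lambdas
        self.lambda_ = float(lambdas[best])
        self.cv_auc_ = mean_auc
        self.coef_ = coef
        self.intercept_ = float(icepts[best])
        self.selected_ = selected
        return self

    def output(self, split_index: int = 0) -> SelectorOutput:
        return SelectorOutput(
            model="elastic_net",
            split_index=split_index,
            selected=list(self.selected_),
            importance={str(n): float(abs(c)) for n, c in
                        zip(self.feature_names_, self.coef_)},
            diagnostics={
                "lambda": self.lambda_,
                "n_nonzero": int(np.count_nonzero(self.coef_)),
                "l1_ratio": self.l1_ratio,
            },
        )


class PlsdaSelector(BaseEstimator):
    """PLS-DA with CV-chosen component count; features ranked by VIP."""

    def __init__(self, max_components: int = 5, folds: int = 5, repeats: int = 10,
                 scale: bool = True, top_k: int = TOP_K, random_state: int | None = 0):
        self.max_components = max_components
        self.folds = folds
        self.repeats = repeats
        self.scale = scale
        self.top_k = top_k
        self.random_state = random_state

    def fit(self, X, y, feature_names=None):
        if self.max_components < 1:
            raise ConfigurationError(
                f"max_components must be >= 1, got {self.max_components}"
            )
        X, yb, classes = _validate_xy(X, y)
        names = np.asarray(feature_names if feature_names is not None else
                           [f"x{i}" for i in range(X.shape[1])])
        max_comp = min(self.max_components, X.shape[0] - 1, X.shape[1])
        ncomp = choose_components_cv(
            X, yb, max_components=max_comp, folds=self.folds,
            repeats=self.repeats, seed=self.random_state, scale=self.scale,
        )
        est = PLSDiscriminant(n_components=ncomp, scale=self.scale).fit(X, yb)
        vip = est.vip()
        order = _rank_features(names, vip, np.arange(len(names)))
        self.feature_names_ = names
        self.n_components_ = est.n_components_
        self.estimator_ = est
        self.vip_ = vip
        self.selected_ = order[: self.top_k]
        return self

    def output(self, split_index: int = 0) -> SelectorOutput:
        return SelectorOutput(
            model="plsda",
            split_index=split_index,
            selected=list(self.selected_),
            importance={str(n): float(v) for n, v in zip(self.feature_names_, self.vip_)},
            diagnostics={"n_components": int(self.n_components_)},
        )


# -- functional wrappers ---------------------------------------------------

def boruta_select(x, y, n_iter: int = 500, conf: float = 0.01,
                  correction: str = "bonferroni", seed: int = 0,
                  feature_names=None, n_estimators: int = 500,
                  split_index: int = 0) -> SelectorOutput:
    sel = BorutaSelector(n_iter=n_iter, conf=conf, correction=correction,
                         n_estimators=n_estimators, random_state=seed)
    return sel.fit(x, y, feature_names=feature_names).output(split_index)


def elasticnet_select(x, y, alpha_mix: float = 0.5, seed: int = 0,
                      feature_names=None, split_index: int = 0) -> SelectorOutput:
    sel = ElasticNetSelector(l1_ratio=alpha_mix, random_state=seed)
    return sel.fit(x, y, feature_names=feature_names).output(split_index)


def plsda_select(x, y, max_components: int = 5, folds: int = 5, repeats: int = 10,
                 seed: int = 0, feature_names=None, split_index: int = 0) -> SelectorOutput:
    sel = PlsdaSelector(max_components=max_components, folds=folds,
                        repeats=repeats, random_state=seed)
    return sel.fit(x, y, feature_names=feature_names).output(split_index)
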