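"""Monte-Carlo cross-validation stability loop, pooled OOF AUC and consensus.

The discovery engine: repeated stratified 70/30 splits of the HC vs
patient-baseline cohort; within each training split, median imputation,
feature selection (top five), z-scoring, and a 1-SE ridge logistic
classifier; the corresponding test split is imputed and standardized with the
*training* parameters and scored without further tuning. Performance is
summarized two ways: the distribution of per-split test AUCs, and a pooled
out-of-fold (OOF) AUC over per-subject median held-out probabilities.
Proteins selected in >= 60% of splits form a selector's stable set; the
consensus panel aggregates the three selectors.

All randomness flows from one root seed through ``numpy.random.SeedSequence``
spawning, so every split, selector and classifier is reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ContractError
from .matrix import ExpressionMatrix, GROUP_HC, GROUP_BASELINE
from .projection import PLSDiscriminant
from .stats import empirical_auc
from .ridge import RidgeLogistic1SE
from .selectors import (
    BorutaSelector,
    ElasticNetSelector,
    PlsdaSelector,
    SelectorOutput,
)

SELECTOR_NAMES = ("boruta", "elastic_net", "plsda")


@dataclass
class SplitPlan:
    split_index: int
    train_ids: list
    test_ids: list
    seed: int


@dataclass
class MccvResult:
    per_split_auc: list[float]
    per_subject_oof: dict[str, list[float]]
    pooled_oof_auc: float
    pooled_oof_ci: tuple[float, float]
    selection_freq: dict[str, float]
    selector_outputs: list[SelectorOutput] = field(default_factory=list, repr=False)

    @property
    def median_auc(self) -> float:
        return float(np.median(self.per_split_auc))

    @property
    def auc_iqr(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.per_split_auc, [25, 75])
        return float(lo), float(hi)


@dataclass
class ConsensusPanel:
    stable_sets: dict[str, list[str]]
    panel: list[str]
    rule: str
    k: int
    stability: float
    aggregate_counts: dict[str, float]
    warnings: list[str] = field(default_factory=list)
    panel_eval: MccvResult | None = None


def make_splits(
    sample_ids,
    labels,
    n_splits: int = 100,
    train_frac: float = 0.7,
    stratified: bool = True,
    seed: int = 0,
) -> list[SplitPlan]:
    """Seeded Monte-Carlo train/test partitions (default 100 x 70/30).

    Stratified by class with nearest-integer rounding of the per-class train
    count (clipped so both partitions keep at least one sample per class);
    train sizes are therefore constant across splits.
    """
    ids = np.asarray(sample_ids)
    y = np.asarray(labels)
    if not 0.0 < train_frac < 1.0:
        raise ConfigurationError(f"train_frac must be in (0, 1), got {train_frac}")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ConfigurationError(
            "each class needs >= 2 samples to appear in both partitions"
        )
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_splits)
    plans = []
    for s, child in enumerate(children):
        rng = np.random.default_rng(child)
        train_idx: list[int] = []
        if stratified:
            for c, n_c in zip(classes, counts):
                idx_c = np.flatnonzero(y == c)
                n_train = int(np.floor(train_frac * n_c + 0.5))
                n_train = min(max(n_train, 1), n_c - 1)
                train_idx.extend(rng.permutation(idx_c)[:n_train])
        else:
            n_train = int(np.floor(train_frac * len(ids) + 0.5))
            n_train = min(max(n_train, 1), len(ids) - 1)
            train_idx = list(rng.permutation(len(ids))[:n_train])
            test_mask = np.ones(len(ids), bool)
            test_mask[train_idx] = False
            if len(set(y[train_idx])) < len(classes) or len(set(y[test_mask])) < len(classes):
                # resample until both partitions carry both classes
                for _ in range(1000):
                    train_idx = list(rng.permutation(len(ids))[:n_train])
                    test_mask = np.ones(len(ids), bool)
                    test_mask[train_idx] = False
                    if (len(set(y[train_idx])) == len(classes)
                            and len(set(y[test_mask])) == len(classes)):
                        break
        train_set = set(train_idx)
        test_idx = [i for i in range(len(ids)) if i not in train_set]
        plans.append(
            SplitPlan(
                split_index=s,
                train_ids=list(ids[sorted(train_set)]),
                test_ids=list(ids[test_idx]),
                seed=int(child.generate_state(1)[0] % (2**31 - 1)),
            )
        )
    return plans


def _diagnostic_frame(matrix: ExpressionMatrix):
    """HC vs patient-baseline design: values, binary labels, subjects."""
    mask = matrix.sample_group.isin([GROUP_HC, GROUP_BASELINE])
    values = matrix.values.loc[mask]
    y = (matrix.sample_group[mask] == GROUP_BASELINE).astype(int)
    subjects = matrix.subject_id[mask]
    return values, y, subjects


def _prepare_split(values: pd.DataFrame, plan: SplitPlan):
    """Train-median imputation and train z-scoring for one split."""
    xtr = values.loc[plan.train_ids].to_numpy(dtype=float)
    xte = values.loc[plan.test_ids].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        med = np.nanmedian(xtr, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    xtr = np.where(np.isnan(xtr), med, xtr)
    xte = np.where(np.isnan(xte), med, xte)
    mean = xtr.mean(axis=0)
    sd = xtr.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (xtr - mean) / sd, (xte - mean) / sd, med, mean, sd


def _make_selector(name: str, seed: int, params: dict | None):
    params = dict(params or {})
    if name == "boruta":
        return BorutaSelector(random_state=seed, **params)
    if name == "elastic_net":
        return ElasticNetSelector(random_state=seed, **params)
    if name == "plsda":
        return PlsdaSelector(random_state=seed, **params)
    raise ConfigurationError(f"unknown selector {name!r}")


def _fit_predict_split(
    ztr, zte, ytr, selector_name, selector, feature_names, ridge_cv, ridge_seed
):
    """Selector + ridge on one prepared split; returns (probs, output)."""
    selector.fit(ztr, ytr, feature_names=feature_names)
    selected = list(selector.selected_)
    out = selector.output()
    if not selected:
        # a fully sparse elastic-net path: no model, predict train prevalence
        prob = np.full(zte.shape[0], float(np.mean(ytr)))
        out.diagnostics["empty_selection"] = True
        return prob, out
    cols = [list(feature_names).index(f) for f in selected]
    xtr_sel, xte_sel = ztr[:, cols], zte[:, cols]
    if selector_name == "plsda":
        # PLS component scores of the selected proteins feed the classifier
        ncomp = min(selector.n_components_, len(cols))
        pls = PLSDiscriminant(n_components=ncomp, scale=False).fit(xtr_sel, ytr)
        xtr_sel = pls.x_scores_
        xte_sel = pls.transform(xte_sel)
        out.diagnostics["ridge_inputs"] = "pls_scores"
    ridge = RidgeLogistic1SE(cv=ridge_cv, random_state=ridge_seed).fit(xtr_sel, ytr)
    prob = ridge.predict_proba(xte_sel)[:, 1]
    out.diagnostics["ridge_lambda"] = float(ridge.lambda_)
    return prob, out


def run_mccv(
    matrix: ExpressionMatrix,
    selector: str,
    splits: list[SplitPlan] | None = None,
    labels: pd.Series | None = None,
    selector_params: dict | None = None,
    ridge_cv: int = 10,
    n_splits: int = 100,
    train_frac: float = 0.7,
    seed: int = 0,
    n_boot: int = 2000,
) -> MccvResult:
    """Run the full MCCV loop for one selector on the HC vs PT_BE design.

    ``selector_params`` are keyword arguments for that selector (e.g.
    ``{"n_iter": 50}`` for Boruta).
    """
    results = run_mccv_all(
        matrix,
        selectors=(selector,),
        splits=splits,
        labels=labels,
        selector_params={selector: dict(selector_params or {})},
        ridge_cv=ridge_cv,
        n_splits=n_splits,
        train_frac=train_frac,
        seed=seed,
        n_boot=n_boot,
    )
    return results[selector]


def run_mccv_all(
    matrix: ExpressionMatrix,
    selectors: tuple[str, ...] = SELECTOR_NAMES,
    splits: list[SplitPlan] | None = None,
    labels: pd.Series | None = None,
    selector_params: dict | None = None,
    ridge_cv: int = 10,
    n_splits: int = 100,
    train_frac: float = 0.7,
    seed: int = 0,
    n_boot: int = 2000,
) -> dict[str, MccvResult]:
    """Run the MCCV loop for several selectors over shared splits.

    Sharing splits (and the per-split imputation/standardization) puts the
    selectors on identical resampling footing, which is what the selection-
    frequency comparison assumes.
    """
    for s in selectors:
        if s not in SELECTOR_NAMES:
            raise ConfigurationError(f"unknown selector {s!r}")
    values, y, subjects = _diagnostic_frame(matrix)
    if labels is not None:
        y = labels.reindex(values.index).astype(int)
    if splits is None:
        splits = make_splits(values.index, y.to_numpy(), n_splits=n_splits,
                             train_frac=train_frac, seed=seed)
    feature_names = list(values.columns)
    params = selector_params or {}

    per_split_auc: dict[str, list[float]] = {s: [] for s in selectors}
    per_subject: dict[str, dict[str, list[float]]] = {s: {} for s in selectors}
    sel_counts: dict[str, dict[str, int]] = {s: dict.fromkeys(feature_names, 0) for s in selectors}
    outputs: dict[str, list[SelectorOutput]] = {s: [] for s in selectors}

    for plan in splits:
        ztr, zte, _, _, _ = _prepare_split(values, plan)
        ytr = y.loc[plan.train_ids].to_numpy()
        yte = y.loc[plan.test_ids].to_numpy()
        if len(np.unique(ytr)) < 2 or len(np.unique(yte)) < 2:
            raise ConfigurationError(
                f"split {plan.split_index}: both classes required in train and test"
            )
        ss = np.random.SeedSequence(plan.seed)
        stage_seeds = [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(2 * len(selectors))]
        for i, name in enumerate(selectors):
            try:
                sel = _make_selector(name, stage_seeds[2 * i], params.get(name))
                prob, out = _fit_predict_split(
                    ztr, zte, ytr, name, sel, feature_names, ridge_cv,
                    stage_seeds[2 * i + 1],
                )
            except Exception as exc:  # annotate with split context
                raise type(exc)(f"split {plan.split_index} ({name}): {exc}") from exc
            out.split_index = plan.split_index
            outputs[name].append(out)
            per_split_auc[name].append(float(empirical_auc(yte, prob)))
            for f in out.selected:
                sel_counts[name][f] += 1
            for sid, p in zip(subjects.loc[plan.test_ids], prob):
                per_subject[name].setdefault(str(sid), []).append(float(p))

    subject_labels = _subject_labels(y, subjects)
    results = {}
    for name in selectors:
        auc, ci = pooled_oof_auc(per_subject[name], subject_labels,
                                 n_boot=n_boot, seed=seed)
        results[name] = MccvResult(
            per_split_auc=per_split_auc[name],
            per_subject_oof=per_subject[name],
            pooled_oof_auc=auc,
            pooled_oof_ci=ci,
            selection_freq={f: c / len(splits) for f, c in sel_counts[name].items()},
            selector_outputs=outputs[name],
        )
    return results


def _subject_labels(y: pd.Series, subjects: pd.Series) -> dict[str, int]:
    lab = {}
    for sid, yi in zip(subjects, y):
        lab[str(sid)] = int(yi)
    return lab


def pooled_oof_auc(
    per_subject_oof: dict[str, list[float]],
    labels: dict[str, int],
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """AUC over per-subject median held-out probabilities, bootstrap CI.

    Subjects never held out are excluded with a warning. The CI resamples
    subjects (stratified by class, seeded, 2.5/97.5 percentiles).
    """
    never = [s for s in labels if s not in per_subject_oof]
    if never:
        warnings.warn(f"{len(never)} subjects never held out; excluded: {never[:5]}")
    subs = [s for s in labels if s in per_subject_oof]
    med = np.array([np.median(per_subject_oof[s]) for s in subs])
    y = np.array([labels[s] for s in subs])
    if len(np.unique(y)) < 2:
        raise ConfigurationError("pooled AUC needs both classes among held-out subjects")
    auc = float(empirical_auc(y, med))
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([
            rng.choice(pos, size=len(pos), replace=True),
            rng.choice(neg, size=len(neg), replace=True),
        ])
        aucs[b] = empirical_auc(y[idx], med[idx])
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return auc, (float(lo), float(hi))


def consensus_panel(
    freqs: dict[str, dict[str, float]],
    stability: float = 0.60,
    rule: str = "top_k_aggregate",
    k: int = 2,
) -> ConsensusPanel:
    """Derive stable sets and the consensus panel from selection frequencies.

    ``top_k_aggregate`` (default) ranks proteins by selection frequency summed
    across selectors and takes the top ``k`` (ties lexicographic);
    ``stable_intersection`` intersects the per-selector >= ``stability``
    stable sets. An empty intersection is reported with a warning suggesting
    the aggregate rule.
    """
    if rule not in ("top_k_aggregate", "stable_intersection"):
        raise ConfigurationError(f"unknown consensus rule {rule!r}")
    universes = [frozenset(f) for f in freqs.values()]
    if len(set(universes)) > 1:
        raise ConfigurationError("selection frequencies must cover the same proteins")
    stable_sets = {
        model: sorted([p for p, f in pf.items() if f >= stability])
        for model, pf in freqs.items()
    }
    agg: dict[str, float] = {}
    for pf in freqs.values():
        for p, f in pf.items():
            agg[p] = agg.get(p, 0.0) + f
    warns: list[str] = []
    if rule == "top_k_aggregate":
        ranked = sorted(agg, key=lambda p: (-agg[p], p))
        panel = ranked[:k]
    else:
        inter = set.intersection(*(set(s) for s in stable_sets.values())) if stable_sets else set()
        panel = sorted(inter)
        if not panel:
            msg = ("stable-set intersection is empty; consider rule='top_k_aggregate'")
            warns.append(msg)
            warnings.warn(msg)
    return ConsensusPanel(
        stable_sets=stable_sets,
        panel=panel,
        rule=rule,
        k=k,
        stability=stability,
        aggregate_counts=agg,
        warnings=warns,
    )


def evaluate_panel(
    panel: list[str],
    matrix: ExpressionMatrix,
    fresh_seed: int = 1,
    n_splits: int = 100,
    train_frac: float = 0.7,
    ridge_cv: int = 10,
    labels: pd.Series | None = None,
    n_boot: int = 2000,
) -> MccvResult:
    """Evaluate a fixed panel on a fresh set of MCCV splits (no reselection)."""
    if not panel:
        raise ConfigurationError("panel must be non-empty")
    missing = [p for p in panel if p not in matrix.protein_ids]
    if missing:
        raise ContractError(f"panel proteins absent from matrix: {missing}")
    values, y, subjects = _diagnostic_frame(matrix)
    if labels is not None:
        y = labels.reindex(values.index).astype(int)
    values = values[list(panel)]
    splits = make_splits(values.index, y.to_numpy(), n_splits=n_splits,
                         train_frac=train_frac, seed=fresh_seed)
    per_split = []
    per_subject: dict[str, list[float]] = {}
    for plan in splits:
        ztr, zte, med, mean, sd = _prepare_split(values, plan)
        ytr = y.loc[plan.train_ids].to_numpy()
        yte = y.loc[plan.test_ids].to_numpy()
        ridge = RidgeLogistic1SE(cv=ridge_cv, random_state=plan.seed).fit(ztr, ytr)
        prob = ridge.predict_proba(zte)[:, 1]
        per_split.append(float(empirical_auc(yte, prob)))
        for sid, p in zip(subjects.loc[plan.test_ids], prob):
            per_subject.setdefault(str(sid), []).append(float(p))
    auc, ci = pooled_oof_auc(per_subject, _subject_labels(y, subjects),
                             n_boot=n_boot, seed=fresh_seed)
    return MccvResult(
        per_split_auc=per_split,
        per_subject_oof=per_subject,
        pooled_oof_auc=auc,
        pooled_oof_ci=ci,
        selection_freq={p: 1.0 for p in panel},
    )
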