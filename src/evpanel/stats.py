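"""Group comparisons, BH correction, volcano classification and single-marker ROC.

Test choice follows a normality gate: a protein tested parametrically
(Student's t / one-way ANOVA) only when every group's values look Gaussian
under a one-sample Kolmogorov–Smirnov test, otherwise non-parametrically
(Wilcoxon rank-sum / Kruskal–Wallis). p-values are Benjamini–Hochberg
adjusted across proteins and reported as q. The volcano rule labels a protein
up/down only when q < 0.05 *and* the group difference exceeds 1 NPX unit
(log2 scale, i.e. a 2-fold change).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigurationError, DataIntegrityError, InsufficientDataError
from .matrix import ExpressionMatrix

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"
DIRECTION_NS = "ns"


@dataclass
class DifferentialResult:
    protein_id: str
    delta_npx: float  # second group minus first, log2 units
    statistic: float
    p_raw: float
    q_bh: float = float("nan")
    test_used: str = ""
    direction: str = DIRECTION_NS


@dataclass
class RocResult:
    marker_id: str
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    youden_threshold: float
    sensitivity: float
    specificity: float
    ci_method: str = "delong"


def normality_gate(values, alpha: float = 0.05, lilliefors: bool = False) -> bool:
    """True when a one-sample KS test against N(mean, sd) has p >= alpha.

    The default uses the KS test with parameters estimated from the sample
    (anti-conservative, but the stated method); ``lilliefors=True`` applies
    the Lilliefors correction instead. A zero-variance sample returns False.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise InsufficientDataError(f"normality gate needs >= 3 values, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        return False
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        _, p = _lf(x, dist="norm")
    else:
        _, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    return bool(p >= alpha)


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DataIntegrityError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def volcano_classify(
    results: list[DifferentialResult],
    q_max: float = 0.05,
    fc_min_log2: float = 1.0,
) -> list[DifferentialResult]:
    """Assign up/down/ns labels in place by the volcano rule (strict inequalities)."""
    for r in results:
        if r.q_bh < q_max and r.delta_npx > fc_min_log2:
            r.direction = DIRECTION_UP
        elif r.q_bh < q_max and r.delta_npx < -fc_min_log2:
            r.direction = DIRECTION_DOWN
        else:
            r.direction = DIRECTION_NS
    return results


def _group_arrays(matrix: ExpressionMatrix, group: str) -> pd.DataFrame:
    vals = matrix.group_values(group)
    if vals.shape[0] == 0:
        raise ConfigurationError(f"group {group!r} has no samples")
    return vals


def two_group_test(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    alpha_normality: float = 0.05,
    paired: bool = False,
    q_max: float = 0.05,
    fc_min_log2: float = 1.0,
) -> list[DifferentialResult]:
    """Per-protein two-group comparison with gate, BH and volcano labels.

    ``delta_npx`` is mean(b) - mean(a). Unpaired by default (Student's t /
    Wilcoxon rank-sum); ``paired=True`` switches to paired t / Wilcoxon
    signed-rank over subjects present at both timepoints. Proteins with fewer
    than 3 non-missing values in either group are excluded with a warning.
    """
    va = _group_arrays(matrix, group_a)
    vb = _group_arrays(matrix, group_b)
    if paired:
        sa = matrix.subject_id[matrix.sample_group == group_a]
        sb = matrix.subject_id[matrix.sample_group == group_b]
        common = sa[sa.isin(sb)].to_numpy()
        va = va.set_axis(sa.to_numpy(), axis=0).loc[common]
        vb = vb.set_axis(sb.to_numpy(), axis=0).loc[common]

    results: list[DifferentialResult] = []
    for pid in matrix.protein_ids:
        a = va[pid].dropna().to_numpy(dtype=float)
        b = vb[pid].dropna().to_numpy(dtype=float)
        if paired:
            pairs = pd.DataFrame({"a": va[pid], "b": vb[pid]}).dropna()
            a, b = pairs["a"].to_numpy(), pairs["b"].to_numpy()
        if len(a) < 3 or len(b) < 3:
            warnings.warn(f"protein {pid}: fewer than 3 values per group; excluded")
            continue
        gaussian = normality_gate(a, alpha_normality) and normality_gate(b, alpha_normality)
        if paired:
            if gaussian:
                stat, p = sps.ttest_rel(b, a)
                test = "t"
            else:
                d = b - a
                if np.all(d == 0):
                    stat, p = 0.0, 1.0
                else:
                    stat, p = sps.wilcoxon(b, a)
                test = "wilcoxon"
        else:
            if gaussian:
                stat, p = sps.ttest_ind(b, a, equal_var=True)
                test = "t"
            else:
                stat, p = sps.ranksums(b, a)
                test = "wilcoxon"
        results.append(
            DifferentialResult(
                protein_id=pid,
                delta_npx=float(np.mean(b) - np.mean(a)),
                statistic=float(stat),
                p_raw=float(p),
                test_used=test,
            )
        )
    _finalize(results, q_max, fc_min_log2)
    return results


def three_group_test(
    matrix: ExpressionMatrix,
    groups: tuple[str, ...] | None = None,
    alpha_normality: float = 0.05,
    q_max: float = 0.05,
) -> list[DifferentialResult]:
    """One-way ANOVA (all groups Gaussian) or Kruskal–Wallis, BH across proteins.

    ``delta_npx`` reports the range of group means (max - min) for effect-size
    context; the volcano rule is not applied to omnibus tests.
    """
    if groups is None:
        groups = tuple(pd.unique(matrix.sample_group))
    if len(groups) < 3:
        raise ConfigurationError(f"three_group_test needs >= 3 groups, got {len(groups)}")
    per_group = {g: _group_arrays(matrix, g) for g in groups}
    results: list[DifferentialResult] = []
    for pid in matrix.protein_ids:
        arrays = [per_group[g][pid].dropna().to_numpy(dtype=float) for g in groups]
        if any(len(a) < 3 for a in arrays):
            warnings.warn(f"protein {pid}: fewer than 3 values in a group; excluded")
            continue
        gaussian = all(normality_gate(a, alpha_normality) for a in arrays)
        if gaussian:
            stat, p = sps.f_oneway(*arrays)
            test = "anova"
        else:
            stat, p = sps.kruskal(*arrays)
            test = "kruskal"
        means = [np.mean(a) for a in arrays]
        results.append(
            DifferentialResult(
                protein_id=pid,
                delta_npx=float(max(means) - min(means)),
                statistic=float(stat),
                p_raw=float(p),
                test_used=test,
            )
        )
    if results:
        q = adjust_bh([r.p_raw for r in results])
        for r, qi in zip(results, q):
            r.q_bh = float(qi)
    return results


def _finalize(results: list[DifferentialResult], q_max: float, fc_min_log2: float) -> None:
    if not results:
        return
    q = adjust_bh([r.p_raw for r in results])
    for r, qi in zip(results, q):
        r.q_bh = float(qi)
    volcano_classify(results, q_max, fc_min_log2)


def empirical_auc(labels, scores) -> float:
    """AUC as P(score_pos > score_neg) with ties counting one half.

    Midrank (Mann–Whitney) formulation; equivalent to the trapezoidal ROC
    area but cheap enough for resampling loops.
    """
    y = np.asarray(labels).astype(bool)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ConfigurationError("AUC needs both classes")
    r = sps.rankdata(s)
    return float((r[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _delong_auc_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance via midrank placements."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    rank_all = sps.rankdata(allv)
    rank_pos = sps.rankdata(pos)
    rank_neg = sps.rankdata(neg)
    v10 = (rank_all[:m] - rank_pos) / n  # placement of each positive
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m  # placement of each negative
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_with_youden(
    scores,
    labels,
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
    marker_id: str = "",
) -> RocResult:
    """Empirical ROC with Youden's-J operating point and an AUC 95% CI.

    AUC is the probability that a positive outscores a negative (ties count
    one half; midrank convention). The operating threshold maximizes
    J = sensitivity + specificity - 1 over observed thresholds; samples with
    score >= threshold are called positive. CI by DeLong (default), falling
    back to a seeded stratified bootstrap when the DeLong variance degenerates
    to zero.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ConfigurationError("labels must contain both classes (0 and 1)")
    if np.unique(s).size < 2:
        raise ConfigurationError("scores must take >= 2 distinct values")

    auc = float(roc_auc_score(y, s))
    fpr, tpr, thr = roc_curve(y, s)
    j = tpr - fpr
    best = int(np.argmax(j))
    sens, spec = float(tpr[best]), float(1.0 - fpr[best])
    threshold = float(thr[best])

    _, var = _delong_auc_variance(s, y)
    if ci_method == "delong" and var > 0:
        se = np.sqrt(var)
        lo, hi = auc - 1.959963984540054 * se, auc + 1.959963984540054 * se
        method = "delong"
    else:
        rng = np.random.default_rng(seed)
        pos_idx = np.flatnonzero(y == 1)
        neg_idx = np.flatnonzero(y == 0)
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            pi = rng.choice(pos_idx, size=len(pos_idx), replace=True)
            ni = rng.choice(neg_idx, size=len(neg_idx), replace=True)
            idx = np.concatenate([pi, ni])
            aucs[b] = roc_auc_score(y[idx], s[idx])
        lo, hi = np.percentile(aucs, [2.5, 97.5])
        method = "bootstrap"
    return RocResult(
        marker_id=marker_id,
        auc=auc,
        auc_ci_low=float(max(0.0, lo)),
        auc_ci_high=float(min(1.0, hi)),
        youden_threshold=threshold,
        sensitivity=sens,
        specificity=spec,
        ci_method=method,
    )


def results_to_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    """Tabulate differential results (one row per protein)."""
    return pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "delta_npx": r.delta_npx,
                "statistic": r.statistic,
                "p_raw": r.p_raw,
                "q_bh": r.q_bh,
                "test_used": r.test_used,
                "direction": r.direction,
            }
            for r in results
        ]
    )
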