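"""Treatment-response analysis: within-patient protein change vs tumor change.

Tumor burden follows RECIST: %dSLD is the percent change of the Sum of
Longest Diameters between baseline and follow-up imaging (negative =
regression). Per protein, the within-patient NPX change (dNPX = follow-up -
baseline) is correlated with %dSLD by Spearman's rho with BH correction
(rho < 0: the protein level increases with tumor regression), and patients
are additionally binned into dNPX quartiles Q1 (most negative change) to Q4
(largest increase), with %dSLD compared between Q1 and Q4 by t-test or
Wilcoxon rank-sum depending on the normality gate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DataIntegrityError, InsufficientDataError
from .matrix import ExpressionMatrix, GROUP_BASELINE, GROUP_FOLLOWUP
from .stats import adjust_bh, normality_gate

QUARTILES = ("Q1", "Q2", "Q3", "Q4")


@dataclass
class ResponseTable:
    """Per-patient tumor-burden change joined with per-protein NPX change."""

    sld_baseline: pd.Series  # mm
    sld_followup: pd.Series  # mm
    pct_delta_sld: pd.Series  # percent
    delta_npx: pd.DataFrame  # subjects x proteins


@dataclass
class QuartileResult:
    test_used: str
    statistic: float
    p_raw: float
    q_bh: float = float("nan")
    sizes: tuple[int, ...] = ()


@dataclass
class ResponseCorrelation:
    protein_id: str
    rho: float
    p_raw: float
    q_bh: float = float("nan")
    quartile_assignment: pd.Series | None = field(default=None, repr=False)
    q1_vs_q4: QuartileResult | None = None


def compute_pct_delta_sld(baseline, followup) -> np.ndarray | float:
    """Percent change in SLD: 100 * (followup - baseline) / baseline."""
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    if np.any(b <= 0):
        raise DataIntegrityError("baseline SLD must be strictly positive")
    out = 100.0 * (f - b) / b
    return float(out) if out.ndim == 0 else out


def build_response_table(matrix: ExpressionMatrix, sld: pd.DataFrame) -> ResponseTable:
    """Join an SLD table (subject_id, sld_baseline, sld_followup) to the cohort.

    dNPX is derived from the matrix as the follow-up minus baseline NPX of
    each subject with both timepoints; subjects lacking follow-up imaging
    (absent from ``sld``) or a follow-up sample are excluded.
    """
    required = {"subject_id", "sld_baseline", "sld_followup"}
    missing = required - set(sld.columns)
    if missing:
        raise DataIntegrityError(f"SLD table missing columns: {sorted(missing)}")
    sld = sld.set_index("subject_id")
    be = matrix.values[matrix.sample_group == GROUP_BASELINE].set_axis(
        matrix.subject_id[matrix.sample_group == GROUP_BASELINE], axis=0
    )
    fu = matrix.values[matrix.sample_group == GROUP_FOLLOWUP].set_axis(
        matrix.subject_id[matrix.sample_group == GROUP_FOLLOWUP], axis=0
    )
    subjects = fu.index.intersection(be.index).intersection(sld.index)
    delta = fu.loc[subjects] - be.loc[subjects]
    b = sld.loc[subjects, "sld_baseline"].astype(float)
    f = sld.loc[subjects, "sld_followup"].astype(float)
    return ResponseTable(
        sld_baseline=b,
        sld_followup=f,
        pct_delta_sld=pd.Series(compute_pct_delta_sld(b, f), index=subjects,
                                name="pct_delta_sld"),
        delta_npx=delta,
    )


def assign_quartiles(delta_npx: pd.Series) -> pd.Series:
    """Rank-based quartile bins Q1..Q4 of a dNPX vector.

    Subjects are ranked by dNPX (ties broken by subject id for determinism)
    and split into four near-equal bins; remainder subjects go to the lower
    quartiles first, so n=27 gives sizes (7, 7, 7, 6). Q1 holds the most
    negative changes.
    """
    order = sorted(delta_npx.index, key=lambda s: (delta_npx[s], str(s)))
    n = len(order)
    base, rem = divmod(n, 4)
    sizes = [base + (1 if i < rem else 0) for i in range(4)]
    labels = {}
    pos = 0
    for qi, size in enumerate(sizes):
        for s in order[pos:pos + size]:
            labels[s] = QUARTILES[qi]
        pos += size
    return pd.Series(labels, name="quartile").reindex(delta_npx.index)


def quartile_compare(
    delta_npx: pd.Series,
    pct_delta_sld: pd.Series,
    alpha_normality: float = 0.05,
) -> tuple[QuartileResult, pd.Series]:
    """Compare %dSLD between the lowest and highest dNPX quartile.

    t-test when both quartiles pass the normality gate, else Wilcoxon
    rank-sum. Returns the test result and the per-subject quartile labels.
    """
    paired = pd.DataFrame({"d": delta_npx, "sld": pct_delta_sld}).dropna()
    if len(paired) < 8:
        raise InsufficientDataError(
            f"quartile comparison needs >= 8 subjects, got {len(paired)}"
        )
    quart = assign_quartiles(paired["d"])
    q1 = paired.loc[quart == "Q1", "sld"].to_numpy()
    q4 = paired.loc[quart == "Q4", "sld"].to_numpy()
    try:
        gaussian = normality_gate(q1, alpha_normality) and normality_gate(q4, alpha_normality)
    except InsufficientDataError:
        gaussian = False
    if gaussian:
        stat, p = sps.ttest_ind(q4, q1, equal_var=True)
        test = "t"
    else:
        stat, p = sps.ranksums(q4, q1)
        test = "wilcoxon"
    sizes = tuple(int((quart == q).sum()) for q in QUARTILES)
    return QuartileResult(test_used=test, statistic=float(stat), p_raw=float(p),
                          sizes=sizes), quart


def spearman_bh(
    delta_npx: pd.DataFrame,
    pct_delta_sld: pd.Series,
    min_pairs: int = 5,
    with_quartiles: bool = True,
) -> list[ResponseCorrelation]:
    """Per-protein Spearman correlation of dNPX with %dSLD, BH across proteins.

    Spearman rho uses midranks; p-values use the t-approximation. Proteins
    with fewer than ``min_pairs`` paired observations, or an all-tied dNPX
    vector, are excluded with a warning. When ``with_quartiles``, the Q1 vs
    Q4 comparison is run per protein and BH-corrected across proteins as a
    second family.
    """
    results: list[ResponseCorrelation] = []
    for pid in delta_npx.columns:
        paired = pd.DataFrame({"d": delta_npx[pid], "sld": pct_delta_sld}).dropna()
        if len(paired) < min_pairs:
            warnings.warn(f"protein {pid}: fewer than {min_pairs} pairs; excluded")
            continue
        if paired["d"].nunique() == 1 or paired["sld"].nunique() == 1:
            warnings.warn(f"protein {pid}: constant vector, rho undefined; excluded")
            continue
        rho, p = sps.spearmanr(paired["d"], paired["sld"])
        rc = ResponseCorrelation(protein_id=pid, rho=float(rho), p_raw=float(p))
        if with_quartiles and len(paired) >= 8:
            rc.q1_vs_q4, rc.quartile_assignment = quartile_compare(
                paired["d"], paired["sld"]
            )
        results.append(rc)
    if results:
        q = adjust_bh([r.p_raw for r in results])
        for r, qi in zip(results, q):
            r.q_bh = float(qi)
        with_q = [r for r in results if r.q1_vs_q4 is not None]
        if with_q:
            qq = adjust_bh([r.q1_vs_q4.p_raw for r in with_q])
            for r, qi in zip(with_q, qq):
                r.q1_vs_q4.q_bh = float(qi)
    return results


def correlations_to_frame(results: list[ResponseCorrelation]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "protein_id": r.protein_id,
            "rho": r.rho,
            "p_raw": r.p_raw,
            "q_bh": r.q_bh,
        }
        if r.q1_vs_q4 is not None:
            row.update(
                q1q4_test=r.q1_vs_q4.test_used,
                q1q4_statistic=r.q1_vs_q4.statistic,
                q1q4_p=r.q1_vs_q4.p_raw,
                q1q4_q=r.q1_vs_q4.q_bh,
            )
        rows.append(row)
    return pd.DataFrame(rows)
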