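"""NPX computation from Ct-level readouts and the protein-level filters.

NPX is derived from qPCR cycle thresholds in three steps:

1. extension-control correction:  dCt  = Ct_analyte - Ct_extension_control
2. inter-plate correction:        ddCt = dCt - dCt_interplate_control
3. correction factor adjustment:  NPX  = correction_factor - ddCt

Higher NPX means more protein (each step flips or shifts the Ct scale, on
which *lower* cycles mean more template).

The analyzable protein set is then defined by two sequential filters: first
remove proteins predominantly below the assay's limit of detection (LOD),
then remove proteins with more than 30% missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataIntegrityError
from .matrix import ExpressionMatrix, GROUP_HC

REQUIRED_CT_COLUMNS = (
    "sample_id",
    "analyte_id",
    "plate_id",
    "ct_analyte",
    "ct_extension_control",
    "dct_interplate_control",
    "correction_factor",
)


@dataclass
class FilterReport:
    """Audit trail of a protein-level filter pass."""

    removed_lod: dict[str, float] = field(default_factory=dict)
    removed_missing: dict[str, float] = field(default_factory=dict)
    n_input: int = 0
    n_retained: int = 0

    @property
    def removed_ids(self) -> set[str]:
        return set(self.removed_lod) | set(self.removed_missing)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "removed_lod": self.removed_lod,
            "removed_missing": self.removed_missing,
        }


def compute_npx(
    readouts: pd.DataFrame,
    sample_group: pd.Series | None = None,
    subject_id: pd.Series | None = None,
) -> ExpressionMatrix:
    """Compute the NPX matrix from long-format Ct readouts.

    ``readouts`` needs one row per (sample, analyte) with the columns named in
    :data:`REQUIRED_CT_COLUMNS`. Control values must be consistent: one
    inter-plate-control dCt per (plate, analyte), one correction factor per
    analyte. Absent (sample, analyte) rows or NaN analyte Ct values yield
    missing cells. Group/subject metadata is optional; samples default to
    unpaired healthy-control labels.
    """
    missing_cols = [c for c in REQUIRED_CT_COLUMNS if c not in readouts.columns]
    if missing_cols:
        raise DataIntegrityError(f"readouts missing required columns: {missing_cols}")

    r = readouts.copy()
    for key, cols in (("analyte_id", ["correction_factor"]),):
        nun = r.groupby(key)[cols].nunique(dropna=False)
        bad = nun[(nun > 1).any(axis=1)]
        if len(bad):
            raise DataIntegrityError(
                f"inconsistent correction factor for analyte {bad.index[0]!r}"
            )
    nun = r.groupby(["plate_id", "analyte_id"])["dct_interplate_control"].nunique(dropna=False)
    bad = nun[nun > 1]
    if len(bad):
        plate, analyte = bad.index[0]
        raise DataIntegrityError(
            f"inconsistent inter-plate control for plate {plate!r}, analyte {analyte!r}"
        )
    for col in ("dct_interplate_control", "correction_factor", "ct_extension_control"):
        nan_rows = r[r[col].isna()]
        if len(nan_rows):
            row = nan_rows.iloc[0]
            raise DataIntegrityError(
                f"missing {col} for plate {row['plate_id']!r}, analyte {row['analyte_id']!r}"
            )

    dct = r["ct_analyte"] - r["ct_extension_control"]
    ddct = dct - r["dct_interplate_control"]
    r["npx"] = r["correction_factor"] - ddct

    if r.duplicated(["sample_id", "analyte_id"]).any():
        dup = r[r.duplicated(["sample_id", "analyte_id"])].iloc[0]
        raise DataIntegrityError(
            f"duplicate readout for sample {dup['sample_id']!r}, analyte {dup['analyte_id']!r}"
        )
    wide = r.pivot(index="sample_id", columns="analyte_id", values="npx")
    wide = wide.loc[r["sample_id"].drop_duplicates(), r["analyte_id"].drop_duplicates()]
    wide.index.name = "sample_id"
    wide.columns.name = None

    if sample_group is None:
        sample_group = pd.Series(GROUP_HC, index=wide.index, name="group")
    else:
        sample_group = sample_group.reindex(wide.index)
    if subject_id is None:
        subject_id = pd.Series(wide.index, index=wide.index, name="subject_id")
    else:
        subject_id = subject_id.reindex(wide.index)
    return ExpressionMatrix(values=wide, sample_group=sample_group, subject_id=subject_id)


def filter_lod(
    matrix: ExpressionMatrix,
    max_below_lod_frac: float = 0.5,
    set_missing: bool = True,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Remove proteins predominantly below the limit of detection.

    A protein is removed when its below-LOD fraction over non-missing cells
    strictly exceeds ``max_below_lod_frac``. In retained proteins, below-LOD
    cells are set missing when ``set_missing`` (the default; they are then
    handled by downstream median imputation), otherwise kept at their
    measured value.
    """
    if not 0.0 <= max_below_lod_frac <= 1.0:
        raise ConfigurationError(
            f"max_below_lod_frac must be in [0, 1], got {max_below_lod_frac!r}"
        )
    observed = matrix.values.notna()
    n_obs = observed.sum(axis=0)
    frac = (matrix.below_lod & observed).sum(axis=0) / n_obs.replace(0, np.nan)
    frac = frac.fillna(0.0)
    drop = frac.index[frac > max_below_lod_frac]
    keep = frac.index[~frac.index.isin(drop)]

    out = matrix.subset_proteins(keep)
    if set_missing:
        out.values = out.values.mask(out.below_lod)
        out.below_lod = out.below_lod & False
    report = FilterReport(
        removed_lod={pid: float(frac[pid]) for pid in drop},
        n_input=matrix.n_proteins,
        n_retained=out.n_proteins,
    )
    return out, report


def filter_missing(
    matrix: ExpressionMatrix, max_missing_frac: float = 0.30
) -> tuple[ExpressionMatrix, FilterReport]:
    """Remove proteins with a missing fraction strictly above the threshold.

    Applied after :func:`filter_lod`, so LOD-induced missingness counts. A
    protein missing in exactly 30% of samples is retained (the rule is
    "more than 30%").
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ConfigurationError(
            f"max_missing_frac must be in [0, 1], got {max_missing_frac!r}"
        )
    frac = matrix.values.isna().mean(axis=0)
    drop = frac.index[frac > max_missing_frac]
    keep = frac.index[~frac.index.isin(drop)]
    out = matrix.subset_proteins(keep)
    report = FilterReport(
        removed_missing={pid: float(frac[pid]) for pid in drop},
        n_input=matrix.n_proteins,
        n_retained=out.n_proteins,
    )
    return out, report


def apply_filters(
    matrix: ExpressionMatrix,
    max_below_lod_frac: float = 0.5,
    max_missing_frac: float = 0.30,
    set_missing: bool = True,
) -> tuple[ExpressionMatrix, FilterReport]:
    """LOD filter followed by the missingness filter, with a merged report."""
    m1, rep1 = filter_lod(matrix, max_below_lod_frac, set_missing=set_missing)
    m2, rep2 = filter_missing(m1, max_missing_frac)
    report = FilterReport(
        removed_lod=rep1.removed_lod,
        removed_missing=rep2.removed_missing,
        n_input=matrix.n_proteins,
        n_retained=m2.n_proteins,
    )
    return m2, report


def reverse_normalization(
    matrix: ExpressionMatrix,
    pre_adjust_conc: pd.Series,
    fixed_conc: float,
) -> ExpressionMatrix:
    """Undo the dilution-to-fixed-concentration step on the log2 scale.

    Samples were diluted to a common protein concentration before assaying;
    shifting each sample's NPX by ``log2(pre_adjust_conc / fixed_conc)``
    restores the pre-dilution scale, enabling the sensitivity re-analysis on
    un-normalized data.
    """
    conc = pre_adjust_conc.reindex(matrix.sample_ids)
    if conc.isna().any():
        missing = conc.index[conc.isna()][0]
        raise DataIntegrityError(f"no pre-adjustment concentration for sample {missing!r}")
    if (conc <= 0).any() or fixed_conc <= 0:
        raise DataIntegrityError("concentrations must be strictly positive")
    shift = np.log2(conc.to_numpy(dtype=float) / float(fixed_conc))
    out = matrix.subset_samples(matrix.sample_ids)
    out.values = out.values.add(shift, axis=0)
    return out
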