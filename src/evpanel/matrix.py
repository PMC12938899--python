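"""The samples x proteins NPX container shared by every pipeline stage.

NPX (Normalized Protein Expression) is a log2-scale relative quantity: a
difference of +1 NPX corresponds to a doubling of protein signal. Values are
stored in a samples x proteins :class:`pandas.DataFrame`; ``NaN`` encodes a
missing measurement. Below-LOD measurements (under the assay's limit of
detection) are *retained* with a boolean flag rather than truncated — the
filtering stage owns the censoring policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataIntegrityError

GROUP_HC = "HC"
GROUP_BASELINE = "PT_BE"
GROUP_FOLLOWUP = "PT_FU"
VALID_GROUPS = (GROUP_HC, GROUP_BASELINE, GROUP_FOLLOWUP)


@dataclass
class ExpressionMatrix:
    """NPX values with group labels, subject pairing and a below-LOD mask.

    Parameters
    ----------
    values : DataFrame
        Samples x proteins NPX values (log2 scale); NaN = missing.
    sample_group : Series
        Per-sample group label, one of ``HC``, ``PT_BE``, ``PT_FU``.
    subject_id : Series
        Per-sample subject identifier. Pairs a patient's baseline (``PT_BE``)
        row with their follow-up (``PT_FU``) row; healthy controls carry their
        own unique subject id.
    below_lod : DataFrame, optional
        Boolean mask, same shape as ``values``; True flags a measurement below
        the protein's limit of detection. Defaults to all-False.
    lod : Series, optional
        Per-protein limit of detection in NPX units (informational).
    """

    values: pd.DataFrame
    sample_group: pd.Series
    subject_id: pd.Series
    below_lod: pd.DataFrame | None = None
    lod: pd.Series | None = None
    _validated: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        if self.below_lod is None:
            self.below_lod = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        self.validate()

    # -- basic views ------------------------------------------------------

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean samples x proteins mask of missing cells (NaN values)."""
        return self.values.isna()

    def group_values(self, group: str) -> pd.DataFrame:
        """NPX values restricted to one sample group."""
        if group not in VALID_GROUPS:
            raise DataIntegrityError(f"unknown group label {group!r}")
        return self.values.loc[self.sample_group == group]

    # -- manipulation ------------------------------------------------------

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        idx = pd.Index(sample_ids)
        missing = idx.difference(self.values.index)
        if len(missing):
            raise DataIntegrityError(f"unknown sample ids: {list(missing)[:5]}")
        return ExpressionMatrix(
            values=self.values.loc[idx].copy(),
            sample_group=self.sample_group.loc[idx].copy(),
            subject_id=self.subject_id.loc[idx].copy(),
            below_lod=self.below_lod.loc[idx].copy(),
            lod=None if self.lod is None else self.lod.copy(),
        )

    def subset_proteins(self, protein_ids) -> "ExpressionMatrix":
        idx = pd.Index(protein_ids)
        missing = idx.difference(self.values.columns)
        if len(missing):
            raise DataIntegrityError(f"unknown protein ids: {list(missing)[:5]}")
        return ExpressionMatrix(
            values=self.values[idx].copy(),
            sample_group=self.sample_group.copy(),
            subject_id=self.subject_id.copy(),
            below_lod=self.below_lod[idx].copy(),
            lod=None if self.lod is None else self.lod.reindex(idx),
        )

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        v, g, s, b = self.values, self.sample_group, self.subject_id, self.below_lod
        if not v.index.is_unique:
            dup = v.index[v.index.duplicated()][0]
            raise DataIntegrityError(f"duplicate sample id {dup!r}")
        if not v.columns.is_unique:
            dup = v.columns[v.columns.duplicated()][0]
            raise DataIntegrityError(f"duplicate protein id {dup!r}")
        if b.shape != v.shape or not b.index.equals(v.index) or not b.columns.equals(v.columns):
            raise DataIntegrityError("below_lod mask does not conform to values shape")
        for name, series in (("sample_group", g), ("subject_id", s)):
            if not series.index.equals(v.index):
                raise DataIntegrityError(f"{name} index does not match sample ids")
        bad = set(g.unique()) - set(VALID_GROUPS)
        if bad:
            raise DataIntegrityError(f"unknown group labels: {sorted(bad)}")
        arr = v.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise DataIntegrityError("non-missing NPX values must be finite")
        # one PT_BE / PT_FU row per subject
        for grp in (GROUP_BASELINE, GROUP_FOLLOWUP):
            sub = s[g == grp]
            if sub.duplicated().any():
                dup = sub[sub.duplicated()].iloc[0]
                raise DataIntegrityError(f"subject {dup!r} has more than one {grp} row")
        hc_subjects = set(s[g == GROUP_HC])
        pt_subjects = set(s[g != GROUP_HC])
        overlap = hc_subjects & pt_subjects
        if overlap:
            raise DataIntegrityError(
                f"HC rows must not share subject ids with patients: {sorted(overlap)[:5]}"
            )
        self._validated = True
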