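"""File formats: the wide NPX CSV dialect, Ct-level CSV, and JSON reports.

The NPX dialect is a single UTF-8 comma-separated table: rows are samples,
the first three columns are ``sample_id``, ``subject_id``, ``group``
(HC / PT_BE / PT_FU), and every further column is one protein. Decimal point
is ".", an empty cell is a missing value. Every writer's output re-parses
under the matching reader.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataIntegrityError
from .matrix import ExpressionMatrix, VALID_GROUPS
from .npx import REQUIRED_CT_COLUMNS, FilterReport
from .synthetic import GroundTruth

META_COLUMNS = ("sample_id", "subject_id", "group")


def read_npx_table(path, lod_mask_path=None) -> ExpressionMatrix:
    """Parse the wide NPX CSV with strict validation.

    ``lod_mask_path`` optionally points to a companion CSV holding the
    boolean below-LOD mask (same sample_id column, 0/1 per protein).
    """
    path = Path(path)
    if not path.exists():
        raise DataIntegrityError(f"no such file: {path}")
    df = pd.read_csv(path, dtype={"sample_id": str, "subject_id": str, "group": str})
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise DataIntegrityError(f"{path.name}: missing metadata columns {missing}")
    protein_cols = [c for c in df.columns if c not in META_COLUMNS]
    if not protein_cols:
        raise DataIntegrityError(f"{path.name}: no protein columns found")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise DataIntegrityError(f"{path.name}: duplicate sample_id {dup!r}")
    bad_groups = set(df["group"].unique()) - set(VALID_GROUPS)
    if bad_groups:
        raise DataIntegrityError(f"{path.name}: unknown group labels {sorted(bad_groups)}")
    values = df[protein_cols].copy()
    for col in protein_cols:
        try:
            values[col] = pd.to_numeric(values[col])
        except (ValueError, TypeError) as exc:
            raise DataIntegrityError(f"{path.name}: non-numeric cell in column {col!r}: {exc}")
    values.index = pd.Index(df["sample_id"], name="sample_id")
    below = None
    if lod_mask_path is not None:
        mask = pd.read_csv(lod_mask_path, dtype={"sample_id": str}).set_index("sample_id")
        below = mask.reindex(index=values.index, columns=values.columns).fillna(0).astype(bool)
    return ExpressionMatrix(
        values=values,
        sample_group=pd.Series(df["group"].to_numpy(), index=values.index, name="group"),
        subject_id=pd.Series(df["subject_id"].to_numpy(), index=values.index, name="subject_id"),
        below_lod=below,
    )


def write_npx_table(matrix: ExpressionMatrix, path, lod_mask_path=None) -> None:
    out = pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "subject_id": matrix.subject_id.to_numpy(),
            "group": matrix.sample_group.to_numpy(),
        }
    )
    out = pd.concat([out.set_index("sample_id"), matrix.values], axis=1)
    out.to_csv(path, index=True)
    if lod_mask_path is not None:
        matrix.below_lod.astype(int).to_csv(lod_mask_path, index=True)


def read_ct_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataIntegrityError(f"no such file: {path}")
    df = pd.read_csv(path, dtype={"sample_id": str, "analyte_id": str, "plate_id": str})
    missing = [c for c in REQUIRED_CT_COLUMNS if c not in df.columns]
    if missing:
        raise DataIntegrityError(f"{path.name}: missing Ct columns {missing}")
    return df


def write_ct_table(readouts: pd.DataFrame, path) -> None:
    readouts.to_csv(path, index=False)


def read_response_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataIntegrityError(f"no such file: {path}")
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "sld_baseline", "sld_followup"}
    missing = required - set(df.columns)
    if missing:
        raise DataIntegrityError(f"{path.name}: missing columns {sorted(missing)}")
    return df


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (pd.Series,)):
        return o.to_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_filter_report(report: FilterReport, json_path, tsv_path=None) -> None:
    write_json(report.to_dict(), json_path)
    if tsv_path is not None:
        rows = [
            {"protein_id": pid, "reason": "below_lod", "fraction": frac}
            for pid, frac in report.removed_lod.items()
        ] + [
            {"protein_id": pid, "reason": "missing", "fraction": frac}
            for pid, frac in report.removed_missing.items()
        ]
        pd.DataFrame(rows, columns=["protein_id", "reason", "fraction"]).to_csv(
            tsv_path, sep="\t", index=False
        )


def write_ground_truth(truth: GroundTruth, path) -> None:
    write_json(asdict(truth), path)


def read_ground_truth(path) -> GroundTruth:
    data = json.loads(Path(path).read_text())
    return GroundTruth(**data)


def write_selection_frequencies(freqs: dict[str, dict[str, float]], path) -> None:
    """Per-selector selection-frequency table (TSV, one row per protein)."""
    proteins = sorted({p for pf in freqs.values() for p in pf})
    df = pd.DataFrame(
        {model: [pf.get(p, 0.0) for p in proteins] for model, pf in freqs.items()},
        index=pd.Index(proteins, name="protein_id"),
    )
    df.to_csv(path, sep="\t")
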