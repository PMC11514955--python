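"""File formats: the cell-table CSV and mutation-table TSV dialects.

Cell tables are wide CSVs (one row per segmented cell) with coordinates in
micrometres, origin top-left, y increasing downward; mutation tables are
MAF-subset TSVs with one row per alteration.  Both readers validate the
schema and raise :class:`SchemaError` naming the offending column or row.
All files are UTF-8 with '.' decimal.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from imgene.genomics import ALTERATION_CLASSES, ONCOGENIC_FLAGS, ACTIONABILITY_LEVELS
from imgene.phenotyping import MARKERS


class SchemaError(ValueError):
    """Raised when an input file violates the documented schema."""


CELL_COLUMNS = ["cell_id", "patient_id", "roi_id", "batch_id",
                "x_um", "y_um", *MARKERS]
MUTATION_COLUMNS = ["patient_id", "gene", "alteration_class", "vaf",
                    "oncogenic", "level"]


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-cell CSV (documented header, um coordinates)."""
    df = pd.read_csv(path)
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cell table missing columns: {missing}")
    for c in ("x_um", "y_um"):
        if not np.all(np.isfinite(df[c].to_numpy(dtype=float))):
            raise SchemaError(f"non-finite coordinates in column {c!r}")
    for m in MARKERS:
        vals = df[m].to_numpy(dtype=float)
        if np.any(vals < 0) or np.any(~np.isfinite(vals)):
            raise SchemaError(f"negative or non-finite intensity in column {m!r}")
    dup = df.duplicated(subset=["roi_id", "cell_id"])
    if dup.any():
        raise SchemaError(
            f"duplicate (roi_id, cell_id) pairs at rows {list(df.index[dup][:5])}")
    return df


def write_cell_table(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cell table missing columns: {missing}")
    df.to_csv(path, index=False)


def read_mutation_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-alteration TSV (MAF-subset dialect).

    VAF must lie in (0, 1] for small variants and may be empty for
    CNVs/fusions; alteration classes, oncogenic flags and evidence levels
    must come from their documented vocabularies.  An empty table is valid
    (zero-mutation patients are allowed).
    """
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "gene": str})
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"mutation table missing columns: {missing}")
    if df.empty:
        return df
    if df["gene"].isna().any() or (df["gene"].str.len() == 0).any():
        raise SchemaError("empty gene symbol")
    bad_class = ~df["alteration_class"].isin(ALTERATION_CLASSES)
    if bad_class.any():
        raise SchemaError(
            f"unknown alteration class at rows {list(df.index[bad_class][:5])}")
    vaf = df["vaf"].to_numpy(dtype=float)
    has_vaf = ~np.isnan(vaf)
    bad_vaf = has_vaf & ((vaf <= 0) | (vaf > 1))
    if bad_vaf.any():
        raise SchemaError(f"VAF outside (0, 1] at rows {list(df.index[bad_vaf][:5])}")
    bad_onc = ~df["oncogenic"].isin(ONCOGENIC_FLAGS)
    if bad_onc.any():
        raise SchemaError(
            f"unknown oncogenic flag at rows {list(df.index[bad_onc][:5])}")
    bad_lvl = ~df["level"].isin(set(ACTIONABILITY_LEVELS) | {"none"})
    if bad_lvl.any():
        raise SchemaError(
            f"unknown actionability level at rows {list(df.index[bad_lvl][:5])}")
    return df


def write_mutation_table(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"mutation table missing columns: {missing}")
    df.to_csv(path, sep="\t", index=False)


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("patient_id", "pn_status"):
        if col not in df.columns:
            raise SchemaError(f"clinical table missing column {col!r}")
    return df
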