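"""Interchange formats: validated CSV/TSV readers and pinned-format writers.

All tables are plain text with explicit headers.  Energies are serialised
with six decimal places so that rerunning a pipeline with the same seed
produces byte-identical files.  The same schemas are accepted from real
MMPBSA/TI post-processing exports.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .esmacs import ENERGY_COMPONENTS

__all__ = [
    "SchemaError",
    "ESMACS_COLUMNS",
    "TI_COLUMNS",
    "COMPOUND_COLUMNS",
    "EDGE_COLUMNS",
    "read_energy_table",
    "read_dudl_table",
    "read_compound_table",
    "read_edge_table",
    "write_energy_table",
    "write_dudl_table",
    "write_compound_table",
    "write_edge_table",
]

FLOAT_FORMAT = "%.6f"

ESMACS_COLUMNS = ("compound_id", "species", "replica", "frame") + ENERGY_COMPONENTS
TI_COLUMNS = ("edge_id", "leg", "lambda", "replica", "frame", "dudl")
COMPOUND_COLUMNS = ("compound_id", "pIC50", "charged", "categories", "censored")
COMPOUND_OPTIONAL = ("minor_cat3", "subgroup")
EDGE_COLUMNS = ("edge_id", "ref_id", "target_id", "ddG_calc", "se_calc", "ddG_exp", "tags")


class SchemaError(ValueError):
    """Header or cell content does not match the declared schema."""


def _check_header(
    df: pd.DataFrame, required: tuple[str, ...], optional: tuple[str, ...], path
) -> None:
    cols = list(df.columns)
    missing = [c for c in required if c not in cols]
    unknown = [c for c in cols if c not in required + optional]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if unknown:
        raise SchemaError(f"{path}: unknown column(s) {unknown}")


def _coerce_numeric(df: pd.DataFrame, columns, path) -> pd.DataFrame:
    for col in columns:
        raw = df[col]
        values = pd.to_numeric(raw, errors="coerce")
        bad = values.isna() & raw.notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise SchemaError(
                f"{path}: non-numeric value {raw[bad.idxmax()]!r} in column "
                f"{col!r} at line {line}"
            )
        if not np.isfinite(values.fillna(0.0)).all():
            raise SchemaError(f"{path}: non-finite value in column {col!r}")
        df[col] = values
    return df


def read_energy_table(path) -> pd.DataFrame:
    """Read and validate an end-point energy CSV (per-frame components)."""
    df = pd.read_csv(path, dtype={"compound_id": str, "species": str})
    _check_header(df, ESMACS_COLUMNS, (), path)
    df = _coerce_numeric(df, ("replica", "frame") + ENERGY_COMPONENTS, path)
    bad_species = set(df["species"].unique()) - {"complex", "receptor", "ligand"}
    if bad_species:
        raise SchemaError(f"{path}: unknown species {sorted(bad_species)}")
    df["replica"] = df["replica"].astype(int)
    df["frame"] = df["frame"].astype(int)
    return df


def read_dudl_table(path) -> pd.DataFrame:
    """Read and validate a ∂U/∂λ CSV."""
    df = pd.read_csv(path, dtype={"edge_id": str, "leg": str})
    _check_header(df, TI_COLUMNS, (), path)
    df = _coerce_numeric(df, ("lambda", "replica", "frame", "dudl"), path)
    df["replica"] = df["replica"].astype(int)
    df["frame"] = df["frame"].astype(int)
    return df


def read_compound_table(path) -> pd.DataFrame:
    """Read and validate the compound TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str, "categories": str})
    _check_header(df, COMPOUND_COLUMNS, COMPOUND_OPTIONAL, path)
    df = _coerce_numeric(df, ("pIC50", "charged", "censored"), path)
    df["categories"] = df["categories"].fillna("")
    return df


def read_edge_table(path) -> pd.DataFrame:
    """Read and validate the transformation-edge TSV."""
    df = pd.read_csv(
        path, sep="\t", dtype={"edge_id": str, "ref_id": str, "target_id": str, "tags": str}
    )
    _check_header(df, EDGE_COLUMNS, (), path)
    df = _coerce_numeric(df, ("ddG_calc", "se_calc", "ddG_exp"), path)
    df["tags"] = df["tags"].fillna("")
    return df


def _write(df: pd.DataFrame, path, sep: str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False, float_format=FLOAT_FORMAT)
    return path


def write_energy_table(df: pd.DataFrame, path) -> Path:
    return _write(df[list(ESMACS_COLUMNS)], path, ",")


def write_dudl_table(df: pd.DataFrame, path) -> Path:
    return _write(df[list(TI_COLUMNS)], path, ",")


def write_compound_table(df: pd.DataFrame, path) -> Path:
    cols = [c for c in COMPOUND_COLUMNS + COMPOUND_OPTIONAL if c in df.columns]
    return _write(df[cols], path, "\t")


def write_edge_table(df: pd.DataFrame, path) -> Path:
    return _write(df[list(EDGE_COLUMNS)], path, "\t")
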