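"""Readers and writers for the pipeline's plain-text exchange formats.

Counts travel as TSV (genes x samples, header row of sample ids), sample
sheets and spectrum reports as CSV, expression matrices as TSV, results as
TSV.  Readers validate the schema and fail fast with the offending file and
column named.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "SchemaError",
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "read_spectra",
    "write_spectra",
    "read_expression",
    "write_expression",
]

DESIGN_COLUMNS = ["sample", "tissue", "treatment", "time_h", "replicate", "plate", "libsize"]
SPECTRUM_COLUMNS = ["scan", "peptide", "protein", "plex", "fraction", "base_peak"] + [
    f"ch{c}" for c in range(1, 9)
]


class SchemaError(ValueError):
    """An input file does not match the expected schema."""


def _require(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise SchemaError(f"{path}: count matrix has no sample columns")
    try:
        df = df.astype(int)
    except (ValueError, TypeError) as err:
        raise SchemaError(f"{path}: counts must be integers ({err})") from err
    if (df < 0).any().any():
        raise SchemaError(f"{path}: counts must be non-negative")
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, DESIGN_COLUMNS, path)
    if df["sample"].duplicated().any():
        raise SchemaError(f"{path}: duplicate sample ids")
    if (df["libsize"] <= 0).any():
        raise SchemaError(f"{path}: libsize must be positive")
    return df


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, index=False)


def read_spectra(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, SPECTRUM_COLUMNS, path)
    if (df["base_peak"] <= 0).any():
        raise SchemaError(f"{path}: base_peak must be positive")
    return df


def write_spectra(spectra: pd.DataFrame, path) -> None:
    spectra.to_csv(path, index=False)


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise SchemaError(f"{path}: expression matrix has no condition columns")
    return df


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_gene_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
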