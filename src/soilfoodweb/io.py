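"""Schema-validated reading and writing of the pipeline's CSV tables.

All tables are UTF-8 comma-separated with a header row; samples are rows
and the first column is the sample ID.  Missing values are written as
empty fields.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A table violates its declared schema."""


@dataclass(frozen=True)
class TableSchema:
    """Column requirements of one table kind.

    ``required`` columns must be present; ``numeric`` columns must parse
    as numbers; ``non_negative`` columns must not contain negatives.
    ``wide`` marks matrix-style tables (counts) whose data columns are
    not fixed in advance: every non-index column is then numeric.
    """

    name: str
    required: tuple = ()
    numeric: tuple = ()
    non_negative: bool = False
    wide: bool = False


NEMATODE_COUNTS = TableSchema("nematode_counts", wide=True, non_negative=True)
OTU_TABLE = TableSchema("otu_table", wide=True, non_negative=True)
TRAITS = TableSchema(
    "traits", required=("genus", "guild", "cp"), numeric=("cp",)
)
TAXONOMY = TableSchema("otu_taxonomy", required=("OTU", "phylum"))
COPY_NUMBERS = TableSchema(
    "copy_numbers", required=("copies_16S",), numeric=("copies_16S",),
    non_negative=True,
)
INCUBATION = TableSchema(
    "incubation",
    required=(
        "O_total", "at_label", "at_excess", "DW", "t", "dCO2", "V",
        "MBC", "DNA_preculture",
    ),
    numeric=(
        "O_total", "at_label", "at_excess", "DW", "t", "dCO2", "V",
        "MBC", "DNA_preculture",
    ),
)
TITRATION = TableSchema(
    "titration",
    required=("c_HCl", "V0", "V1"),
    numeric=("c_HCl", "V0", "V1"),
)
CHEMISTRY = TableSchema(
    "chemistry",
    required=("treatment", "pH", "SOC", "TN", "TP", "TK", "CEC", "MBC"),
    numeric=("pH", "SOC", "TN", "TP", "TK", "CEC", "MBC"),
)


def read_table(path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a CSV table against ``schema``.

    The first column is used as the index (sample/genus/OTU ID).
    Violations raise :class:`SchemaError` naming the offending column and
    row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path, index_col=0)

    missing = [c for c in schema.required if c not in df.columns
               and c != df.index.name]
    if missing:
        raise SchemaError(
            f"{schema.name} table {path} missing column(s): {missing}"
        )
    numeric_cols = list(schema.numeric) if not schema.wide else list(df.columns)
    for col in numeric_cols:
        if col == df.index.name:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        if bad.any():
            row = df.index[bad][0]
            raise SchemaError(
                f"{schema.name} table {path}: non-numeric value in column "
                f"{col!r}, row {row!r}"
            )
        df[col] = coerced
    if schema.non_negative:
        check = df[numeric_cols] if numeric_cols else df
        arr = check.to_numpy(dtype=float)
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise SchemaError(
                f"{schema.name} table {path}: negative value at row "
                f"{check.index[i]!r}, column {check.columns[j]!r}"
            )
    return df


def write_table(df: pd.DataFrame, path, *, index_label: str = "sample") -> None:
    """Write a table as UTF-8 CSV, missing values as empty fields."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=True, index_label=index_label, na_rep="")
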