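"""Canonical tab-separated table I/O.

All pipeline artefacts are plain TSV: header row, tab delimiter, 'NA' for
missing, reals at six significant digits (exact integers written as
integers).  Reading back a canonically written file and writing it again
is byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_table", "write_table", "read_counts", "write_counts"]

NA = "NA"


def _format_cell(x) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return NA
    if isinstance(x, (bool, np.bool_)):
        return "1" if x else "0"
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if isinstance(x, (float, np.floating)):
        if float(x).is_integer() and abs(x) < 1e15:
            return str(int(x))
        return f"{x:.6g}"
    return str(x)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df = df.reset_index() if index else df
    lines = ["\t".join(map(str, df.columns))]
    for row in df.itertuples(index=False):
        lines.append("\t".join(_format_cell(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_table(
    path: str | Path,
    required: list[str] | None = None,
    numeric: list[str] | None = None,
    unique: str | None = None,
) -> pd.DataFrame:
    """Read a TSV with schema checks that name the offending file/column."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path.name}: missing column(s) {missing}")
    for col in numeric or []:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as err:
            raise ValueError(f"{path.name}: non-numeric cell in column '{col}'") from err
    if unique is not None and df[unique].duplicated().any():
        dups = sorted(df[unique][df[unique].duplicated()].astype(str).unique())
        raise ValueError(f"{path.name}: duplicate {unique}(s): {dups[:5]}")
    return df


def write_counts(frame: pd.DataFrame, path: str | Path) -> None:
    """Gene x sample integer counts with a leading gene_id column."""
    out = frame.reset_index()
    out.columns = ["gene_id", *frame.columns]
    write_table(out, path)


def read_counts(path: str | Path):
    from .prep import CountMatrix

    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError(f"{path.name}: missing column(s) ['gene_id']")
    if df["gene_id"].duplicated().any():
        dups = sorted(df["gene_id"][df["gene_id"].duplicated()].astype(str).unique())
        raise ValueError(f"{path.name}: duplicate gene_id(s): {dups[:5]}")
    genes = list(df["gene_id"].astype(str))
    mat = df.drop(columns="gene_id")
    try:
        counts = mat.to_numpy(dtype=np.int64)
    except (ValueError, TypeError) as err:
        raise ValueError(f"{path.name}: non-integer cell in count matrix") from err
    return CountMatrix(genes, list(mat.columns), counts)
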