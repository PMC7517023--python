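"""Reading and writing interaction matrices as delimited text.

The default dialect is a labeled TSV: first column holds row (X set)
labels, header row holds column (Y set) labels.  ``headerless`` reads a
bare numeric table and synthesizes labels X1.., Y1..  Written and re-read
matrices round-trip exactly, labels included.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import InteractionMatrix

__all__ = ["DIALECTS", "read_matrix", "write_matrix"]

DIALECTS = ("labeled_tsv", "labeled_csv", "headerless")


def _sep(dialect: str) -> str:
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    return "," if dialect == "labeled_csv" else "\t"


def read_matrix(path, dialect: str = "labeled_tsv") -> InteractionMatrix:
    """Read an interaction matrix (rows = X set, columns = Y set).

    Errors on ragged rows and on negative or non-numeric cells, naming
    the offending location.
    """
    path = Path(path)
    sep = _sep(dialect)
    try:
        if dialect == "headerless":
            df = pd.read_csv(path, sep=sep, header=None)
        else:
            df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table ({exc})") from exc
    if df.empty:
        raise ValueError(f"{path}: empty table")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"{path}: non-numeric or missing cell at row {df.index[i]!r}, "
            f"column {df.columns[j]!r} (ragged rows appear as missing cells)"
        )
    neg = np.argwhere(values < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(
            f"{path}: negative entry {values[i, j]:g} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    if dialect == "headerless":
        return InteractionMatrix.from_array(values)
    return InteractionMatrix.from_array(
        values,
        row_labels=tuple(str(x) for x in df.index),
        col_labels=tuple(str(x) for x in df.columns),
    )


def write_matrix(matrix: InteractionMatrix, path, dialect: str = "labeled_tsv") -> None:
    """Write a matrix so that :func:`read_matrix` recovers it exactly."""
    path = Path(path)
    sep = _sep(dialect)
    df = pd.DataFrame(
        matrix.values, index=list(matrix.row_labels), columns=list(matrix.col_labels)
    )
    if dialect == "headerless":
        df.to_csv(path, sep=sep, header=False, index=False)
    else:
        df.to_csv(path, sep=sep)
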