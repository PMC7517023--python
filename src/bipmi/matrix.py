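"""Labeled bipartite interaction (incidence) matrices.

An interaction matrix records interactions between two sets of species:
rows are the X set (e.g. plants), columns the Y set (e.g. pollinators).
Entries are non-negative integer interaction counts; a binary matrix
records presence/absence only.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DegenerateMatrixError(ValueError):
    """Raised for matrices on which the requested quantity is undefined."""


def _as_count_array(values) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 2:
        raise ValueError(f"interaction matrix must be 2-D, got ndim={arr.ndim}")
    if arr.size == 0:
        raise ValueError("interaction matrix must have at least one row and column")
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"interaction matrix must be numeric, got dtype={arr.dtype}")
    if np.any(arr < 0):
        i, j = np.argwhere(arr < 0)[0]
        raise ValueError(f"negative entry {arr[i, j]} at row {i}, column {j}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
            bad = np.argwhere(~np.isfinite(arr) | (arr != np.floor(arr)))
            i, j = bad[0]
            raise ValueError(
                f"non-integer entry {arr[i, j]} at row {i}, column {j}; "
                "interaction counts must be non-negative integers"
            )
    arr = arr.astype(np.int64)
    if not arr.any():
        raise DegenerateMatrixError("all-zero matrix: no interactions recorded")
    return arr


@dataclass(frozen=True)
class InteractionMatrix:
    """Adjacency matrix a_ij of a bipartite interaction network.

    Parameters
    ----------
    values
        Non-negative integer counts, shape ``(NX, NY)``. At least one
        entry must be positive.
    row_labels, col_labels
        Unique species labels for the X (row) and Y (column) sets.
    """

    values: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = _as_count_array(self.values)
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)
        rows = tuple(str(x) for x in self.row_labels)
        cols = tuple(str(x) for x in self.col_labels)
        if len(rows) != arr.shape[0]:
            raise ValueError(f"{len(rows)} row labels for {arr.shape[0]} rows")
        if len(cols) != arr.shape[1]:
            raise ValueError(f"{len(cols)} column labels for {arr.shape[1]} columns")
        if len(set(rows)) != len(rows):
            raise ValueError("row labels must be unique")
        if len(set(cols)) != len(cols):
            raise ValueError("column labels must be unique")
        object.__setattr__(self, "row_labels", rows)
        object.__setattr__(self, "col_labels", cols)

    @classmethod
    def from_array(cls, values, row_labels=None, col_labels=None) -> "InteractionMatrix":
        """Build a matrix, synthesizing labels X1.., Y1.. when absent."""
        arr = np.asarray(values)
        if arr.ndim != 2:
            raise ValueError("interaction matrix must be 2-D")
        if row_labels is None:
            row_labels = tuple(f"X{i + 1}" for i in range(arr.shape[0]))
        if col_labels is None:
            col_labels = tuple(f"Y{j + 1}" for j in range(arr.shape[1]))
        return cls(arr, tuple(row_labels), tuple(col_labels))

    @property
    def nx(self) -> int:
        return self.values.shape[0]

    @property
    def ny(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def is_binary(self) -> bool:
        return bool(self.values.max() <= 1)

    def with_values(self, values) -> "InteractionMatrix":
        """Same labels, new counts (shape must match)."""
        arr = np.asarray(values)
        if arr.shape != self.shape:
            raise ValueError(f"shape {arr.shape} != {self.shape}")
        return InteractionMatrix(arr, self.row_labels, self.col_labels)

    def __eq__(self, other) -> bool:
        if not isinstance(other, InteractionMatrix):
            return NotImplemented
        return (
            self.row_labels == other.row_labels
            and self.col_labels == other.col_labels
            and np.array_equal(self.values, other.values)
        )

    def __hash__(self):
        return hash((self.row_labels, self.col_labels, self.values.tobytes()))
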