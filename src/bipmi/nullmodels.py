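"""Degree-preserving swaps and topology metrics (NODF, bipartite modularity).

A checkerboard swap replaces a 2x2 submatrix [[1,0],[0,1]] by
[[0,1],[1,0]] (or vice versa) on some pair of rows and columns.  It
conserves every row and column sum, hence occupancy, degree
distributions and the whole entropy decomposition — while nestedness and
modularity are free to change.  Running sequential swaps on a structured
matrix therefore separates what mutual information measures (the margins)
from what topology metrics measure (the arrangement).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .matrix import InteractionMatrix
from .metrics import decompose

__all__ = [
    "SwapRigidError",
    "SwapTrajectory",
    "checkerboard_swap",
    "shuffle_preserving_degrees",
    "nodf",
    "modularity",
    "detect_modules",
    "swap_experiment",
]


class SwapRigidError(ValueError):
    """The matrix contains no 2x2 checkerboard: no swap can be applied."""


def _is_checkerboard(sub: np.ndarray) -> bool:
    return (sub[0, 0] == sub[1, 1]) and (sub[0, 1] == sub[1, 0]) and (sub[0, 0] != sub[0, 1])


def _find_checkerboard(a: np.ndarray, rng: np.random.Generator):
    """Row pair and column pair holding a checkerboard, or raise.

    Rejection sampling (two random rows, two random columns) with a cap of
    10*NX*NY tries, then an exhaustive scan.  Rejection is not exactly
    uniform over checkerboards, which is immaterial here: every swap
    conserves the margins regardless of which checkerboard is chosen.
    """
    nx, ny = a.shape
    if nx < 2 or ny < 2:
        raise SwapRigidError("matrix smaller than 2x2 admits no swap")
    for _ in range(10 * nx * ny):
        r = rng.choice(nx, size=2, replace=False)
        c = rng.choice(ny, size=2, replace=False)
        if _is_checkerboard(a[np.ix_(r, c)]):
            return r, c
    candidates = [
        (r, c)
        for r in combinations(range(nx), 2)
        for c in combinations(range(ny), 2)
        if _is_checkerboard(a[np.ix_(r, c)])
    ]
    if not candidates:
        raise SwapRigidError(
            "swap-rigid matrix: no 2x2 checkerboard submatrix exists"
        )
    r, c = candidates[rng.integers(len(candidates))]
    return np.asarray(r), np.asarray(c)


def _swap_inplace(a: np.ndarray, rng: np.random.Generator) -> None:
    r, c = _find_checkerboard(a, rng)
    sub = a[np.ix_(r, c)]
    a[np.ix_(r, c)] = 1 - sub


def checkerboard_swap(matrix: InteractionMatrix, seed: int | None = None) -> InteractionMatrix:
    """One degree-preserving swap on a binary matrix.

    Returns a new matrix differing in exactly four cells; all row and
    column sums are conserved.  Raises :class:`SwapRigidError` when no
    checkerboard exists.
    """
    if not matrix.is_binary:
        raise ValueError("checkerboard swaps are defined for binary matrices")
    a = matrix.values.copy()
    _swap_inplace(a, np.random.default_rng(seed))
    return matrix.with_values(a)


def shuffle_preserving_degrees(
    a: np.ndarray, n_swaps: int, rng: np.random.Generator
) -> None:
    """Apply up to ``n_swaps`` swaps in place; stops early if swap-rigid."""
    for _ in range(n_swaps):
        try:
            _swap_inplace(a, rng)
        except SwapRigidError:
            return


def nodf(matrix: InteractionMatrix) -> float:
    """Nestedness by overlap and decreasing fill, on a 0-100 scale.

    For every pair of rows (and of columns): if the two marginal totals
    are equal the pair contributes 0; otherwise it contributes
    100 * (shared interactions) / (smaller marginal total).  NODF is the
    mean over all row pairs and column pairs.
    """
    if not matrix.is_binary:
        raise ValueError("NODF is defined for binary matrices")
    nx, ny = matrix.shape
    if nx < 2 or ny < 2:
        raise ValueError("NODF requires at least 2 rows and 2 columns")
    total = 0.0
    for a in (matrix.values, matrix.values.T):
        deg = a.sum(axis=1)
        overlap = a @ a.T
        n = len(deg)
        iu, ju = np.triu_indices(n, k=1)
        lesser = np.minimum(deg[iu], deg[ju])
        counted = (deg[iu] != deg[ju]) & (lesser > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            contrib = np.where(counted, 100.0 * overlap[iu, ju] / lesser, 0.0)
        total += contrib.sum()
    n_pairs = nx * (nx - 1) // 2 + ny * (ny - 1) // 2
    return float(total / n_pairs)


def modularity(matrix: InteractionMatrix, row_modules, col_modules) -> float:
    """Barber bipartite modularity Q for a given module partition.

    Q = sum_k (e_kk - a_k * b_k): the fraction of interactions inside
    module k minus the product of its row-side and column-side marginal
    interaction fractions.  Q = 1 - 1/m for m equal fully occupied
    diagonal blocks; Q = 0 when interactions follow the margins.
    """
    row_modules = np.asarray(row_modules)
    col_modules = np.asarray(col_modules)
    if row_modules.shape != (matrix.nx,):
        raise ValueError(
            f"row partition covers {row_modules.size} rows, matrix has {matrix.nx}"
        )
    if col_modules.shape != (matrix.ny,):
        raise ValueError(
            f"column partition covers {col_modules.size} columns, matrix has {matrix.ny}"
        )
    a = matrix.values
    nm = a.sum()
    q = 0.0
    for k in set(row_modules.tolist()) | set(col_modules.tolist()):
        rmask = row_modules == k
        cmask = col_modules == k
        e_kk = a[np.ix_(rmask, cmask)].sum() / nm
        a_k = a[rmask, :].sum() / nm
        b_k = a[:, cmask].sum() / nm
        q += e_kk - a_k * b_k
    return float(q)


def detect_modules(
    matrix: InteractionMatrix, seed: int | None = None, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Heuristic module partition by bipartite label propagation.

    Columns start in singleton modules; rows and columns then repeatedly
    adopt the interaction-weighted majority label of their partners until
    stable.  A greedy heuristic only — use the planted partition whenever
    the generator is known.
    """
    a = matrix.values
    rng = np.random.default_rng(seed)
    col_lab = np.arange(matrix.ny)
    row_lab = np.zeros(matrix.nx, dtype=np.int64)
    for _ in range(max_iter):
        prev = (row_lab.copy(), col_lab.copy())
        for i in rng.permutation(matrix.nx):
            w = np.bincount(col_lab, weights=a[i, :])
            if w.any():
                row_lab[i] = int(np.argmax(w))
        for j in rng.permutation(matrix.ny):
            w = np.bincount(row_lab, weights=a[:, j])
            if w.any():
                col_lab[j] = int(np.argmax(w))
        if np.array_equal(row_lab, prev[0]) and np.array_equal(col_lab, prev[1]):
            break
    return row_lab, col_lab


@dataclass(frozen=True)
class SwapTrajectory:
    """Metrics recorded along a sequence of degree-preserving swaps."""

    step: np.ndarray
    s: np.ndarray
    nodf: np.ndarray
    q: np.ndarray
    matrix_snapshots: dict[int, InteractionMatrix] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"step": self.step, "S": self.s, "NODF": self.nodf, "Q": self.q})


def swap_experiment(
    spec_or_matrix,
    n_swaps: int,
    record_every: int = 1,
    seed: int | None = None,
    partition=None,
    snapshot_steps=(),
) -> SwapTrajectory:
    """Track S, NODF and modularity along sequential swaps.

    ``spec_or_matrix`` is a :class:`~bipmi.generators.TopologySpec` (the
    planted partition is then used for Q) or an
    :class:`~bipmi.matrix.InteractionMatrix` (pass ``partition=(row_modules,
    col_modules)`` or the label-propagation heuristic is used).  Each step
    counts one accepted swap; metrics are recorded at step 0, every
    ``record_every`` steps, and at the final step.
    """
    from .generators import TopologySpec, generate, planted_modules

    if isinstance(spec_or_matrix, TopologySpec):
        matrix = generate(spec_or_matrix)
        if partition is None:
            partition = planted_modules(spec_or_matrix)
    elif isinstance(spec_or_matrix, InteractionMatrix):
        matrix = spec_or_matrix
    else:
        raise TypeError("expected a TopologySpec or an InteractionMatrix")
    if partition is None:
        partition = detect_modules(matrix, seed=seed)
    row_mod, col_mod = partition
    if n_swaps < 0:
        raise ValueError("n_swaps must be >= 0")
    if record_every < 1:
        raise ValueError("record_every must be >= 1")

    a = matrix.values.copy()
    rng = np.random.default_rng(seed)
    snapshot_steps = set(snapshot_steps)
    steps, s_vals, nodf_vals, q_vals = [], [], [], []
    snapshots: dict[int, InteractionMatrix] = {}

    def record(step: int) -> None:
        current = matrix.with_values(a)
        steps.append(step)
        s_vals.append(decompose(current).s)
        nodf_vals.append(nodf(current))
        q_vals.append(modularity(current, row_mod, col_mod))
        if step in snapshot_steps:
            snapshots[step] = current

    record(0)
    for step in range(1, n_swaps + 1):
        _swap_inplace(a, rng)
        if step % record_every == 0 or step == n_swaps:
            record(step)
    return SwapTrajectory(
        step=np.asarray(steps),
        s=np.asarray(s_vals),
        nodf=np.asarray(nodf_vals),
        q=np.asarray(q_vals),
        matrix_snapshots=snapshots,
    )
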