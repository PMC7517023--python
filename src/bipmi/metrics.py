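"""Entropy decomposition of an interaction matrix.

The species marginal distributions p_i(X) = k_i/NM and p_j(Y) = k_j/NM and
the cell distribution p_l(X,Y) = a_l/NM yield the entropies H(X), H(Y) and
the joint entropy H(X,Y).  The mutual information

    I(X;Y) = H(X) + H(Y) - H(X,Y)

measures reciprocal specialization: how much knowing a species' partner
reduces uncertainty about the species itself.  Its normalization

    S = I(X;Y) / H(X,Y),  0 <= S <= 1

is the headline structure measure; S = 1 for a diagonal (perfectly
biunique) matrix and S = 0 for a fully occupied one.  H2' instead
normalizes I by its maximum given the marginal totals.

All entropies default to natural logarithms; S and H2' are ratios of
entropies and therefore identical under any log base.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import entropy as _shannon

from .matrix import DegenerateMatrixError, InteractionMatrix

__all__ = [
    "MarginSummary",
    "EntropyDecomposition",
    "margins",
    "entropy",
    "decompose",
    "h2prime",
]

#: accepted log bases; None means natural log for scipy
_BASES = {"e": None, "nats": None, "2": 2.0, "bits": 2.0, "10": 10.0}

_P_RTOL = 1e-9  # relative tolerance for probability normalization


def _resolve_base(base) -> float | None:
    if isinstance(base, str):
        try:
            return _BASES[base]
        except KeyError:
            raise ValueError(f"unknown log base {base!r}; use 'e', 2 or 10") from None
    if base in (2, 10):
        return float(base)
    raise ValueError(f"unknown log base {base!r}; use 'e', 2 or 10")


@dataclass(frozen=True)
class MarginSummary:
    """Marginal totals (species degrees) of an interaction matrix.

    ``kx[i] = sum_j a_ij`` and ``ky[j] = sum_i a_ij`` are the per-species
    interaction totals; ``nm`` is the grand total and ``rho`` the occupancy
    (connectance): the fraction of cells with at least one interaction.
    """

    kx: np.ndarray
    ky: np.ndarray
    nm: int
    rho: float


@dataclass(frozen=True)
class EntropyDecomposition:
    """H(X), H(Y), H(X,Y), I(X;Y), S and H2' for one matrix.

    ``hx``, ``hy``, ``hxy`` and ``mi`` are in the units of ``log_base``
    (nats by default); ``s`` and ``h2prime`` are dimensionless and
    base-free.  ``h2prime`` is NaN when the marginal totals admit a single
    contingency table (its normalization is then 0/0).
    """

    hx: float
    hy: float
    hxy: float
    mi: float
    s: float
    h2prime: float
    log_base: str = "e"


def margins(matrix: InteractionMatrix) -> MarginSummary:
    """Row/column totals, grand total NM and occupancy rho of a matrix.

    For binary matrices rho = NM/(NX*NY); for weighted matrices NM is the
    weighted total while rho still counts occupied cells.
    """
    a = matrix.values
    kx = a.sum(axis=1)
    ky = a.sum(axis=0)
    nm = int(a.sum())
    rho = np.count_nonzero(a) / a.size
    return MarginSummary(kx=kx, ky=ky, nm=nm, rho=rho)


def entropy(p, base="e") -> float:
    """Shannon entropy -sum p_i log p_i of a probability vector.

    Terms with p_i = 0 contribute nothing.  Raises on negative entries or
    when the probabilities do not sum to 1 (relative tolerance 1e-9).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("probability vector must be 1-D")
    if np.any(p < 0):
        raise ValueError(f"negative probability {p[p < 0][0]}")
    total = p.sum()
    if not math.isclose(total, 1.0, rel_tol=_P_RTOL):
        raise ValueError(f"probabilities sum to {total}, not 1")
    return float(_shannon(p, base=_resolve_base(base)))


def _entropies(matrix: InteractionMatrix) -> tuple[float, float, float]:
    """(H(X), H(Y), H(X,Y)) in nats."""
    a = matrix.values
    nm = a.sum()
    hx = float(_shannon(a.sum(axis=1) / nm))
    hy = float(_shannon(a.sum(axis=0) / nm))
    hxy = float(_shannon(a.ravel() / nm))
    return hx, hy, hxy


def decompose(matrix: InteractionMatrix, base="e") -> EntropyDecomposition:
    """Full entropy decomposition of an interaction matrix.

    Raises :class:`DegenerateMatrixError` when only one cell is occupied:
    then H(X,Y) = 0 and S = I/H(X,Y) is undefined.
    """
    scale = _resolve_base(base)
    factor = 1.0 if scale is None else 1.0 / math.log(scale)
    if np.count_nonzero(matrix.values) < 2:
        raise DegenerateMatrixError(
            "single occupied cell: H(X,Y)=0, normalized mutual information undefined"
        )
    hx, hy, hxy = _entropies(matrix)
    mi = hx + hy - hxy
    s = mi / hxy
    # I >= 0 analytically; guard the floating-point residue only
    if -1e-9 < s < 0.0:
        s = 0.0
    elif 1.0 < s < 1.0 + 1e-9:
        s = 1.0
    try:
        h2 = h2prime(matrix)
    except (ValueError, DegenerateMatrixError):
        h2 = float("nan")
    return EntropyDecomposition(
        hx=hx * factor,
        hy=hy * factor,
        hxy=hxy * factor,
        mi=mi * factor,
        s=float(s),
        h2prime=h2,
        log_base=str(base),
    )


def _greedy_min_joint_entropy(kx: np.ndarray, ky: np.ndarray) -> float:
    """Heuristic minimal H(X,Y) over tables with the given margins.

    Greedy packing: repeatedly place the largest feasible count at the
    (row, column) pair with the largest remaining margins.  Concentrating
    mass in few cells drives the joint entropy down; the result is an
    upper bound on I(X;Y)max (exact on all small cases exercised in the
    test suite, but not guaranteed optimal in general).
    """
    kx = kx.astype(np.int64).copy()
    ky = ky.astype(np.int64).copy()
    nm = kx.sum()
    cells: list[int] = []
    while kx.any():
        i = int(np.argmax(kx))
        j = int(np.argmax(ky))
        c = int(min(kx[i], ky[j]))
        cells.append(c)
        kx[i] -= c
        ky[j] -= c
    p = np.asarray(cells, dtype=float) / nm
    return float(_shannon(p))


def h2prime(matrix: InteractionMatrix) -> float:
    """Specialization index H2': mutual information over its maximum
    given the marginal totals.

    Computed as (H(X,Y)max - H(X,Y)) / (H(X,Y)max - H(X,Y)min) with
    H(X,Y)max = H(X) + H(Y) (independence) and H(X,Y)min from a greedy
    packing heuristic; clamped to [0, 1].  Raises when the margins admit
    only a single table (e.g. a 1x1 matrix), where H2' is 0/0.
    """
    hx, hy, hxy = _entropies(matrix)
    ms = margins(matrix)
    hxy_min = _greedy_min_joint_entropy(ms.kx, ms.ky)
    denom = (hx + hy) - hxy_min
    if denom <= 1e-12:
        raise ValueError(
            "marginal totals admit a single contingency table; H2' is undefined"
        )
    q = ((hx + hy) - hxy) / denom
    return float(min(max(q, 0.0), 1.0))
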