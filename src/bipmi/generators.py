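"""Generators for the model matrix families.

Families
--------
uniform_regular
    Square binary matrix with every row and column sum equal to k = rho*N.
random_fill
    Binary matrix with a fixed number of occupied cells placed uniformly
    at random; margins free to vary.
nested_packed
    Square matrix packed above the antidiagonal: row degrees N, N-1, .., 1.
nested_general
    Perfectly nested binary matrix of any shape at a target occupancy.
modular_isometric / modular_rect
    Block-diagonal matrices of m full t x t (or t x z) modules.
modular_increasing
    Square blocks of sides 1, 2, .., m on the diagonal.
compound_nested
    m diagonal blocks, each internally the t x t packed nested pattern.

All stochastic generators take a seed and are bit-reproducible.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .matrix import InteractionMatrix

__all__ = [
    "TopologySpec",
    "generate",
    "planted_modules",
    "uniform_regular",
    "random_fill",
    "nested_packed",
    "nested_general",
    "modular_isometric",
    "modular_rect",
    "modular_increasing",
    "compound_nested",
]

FAMILIES = (
    "uniform_regular",
    "random_fill",
    "nested_packed",
    "nested_general",
    "modular_isometric",
    "modular_rect",
    "modular_increasing",
    "compound_nested",
)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _labeled(values: np.ndarray) -> InteractionMatrix:
    return InteractionMatrix.from_array(values)


@dataclass(frozen=True)
class TopologySpec:
    """Parameters of one generated matrix family.

    Only the fields a family uses need to be set: ``n`` (square side) or
    ``nx``/``ny``, occupancy ``rho``, module count ``m``, module sides
    ``t`` and ``z``, and ``seed`` for the stochastic families.
    """

    family: str
    n: int | None = None
    nx: int | None = None
    ny: int | None = None
    rho: float | None = None
    m: int | None = None
    t: int | None = None
    z: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; choose from {', '.join(FAMILIES)}"
            )


def _require(spec: TopologySpec, *fields: str) -> list:
    out = []
    for f in fields:
        v = getattr(spec, f)
        if v is None:
            raise ValueError(f"family {spec.family!r} requires parameter {f!r}")
        out.append(v)
    return out


def generate(spec: TopologySpec) -> InteractionMatrix:
    """Build the matrix described by a :class:`TopologySpec`."""
    fam = spec.family
    if fam == "uniform_regular":
        n, rho = _require(spec, "n", "rho")
        return uniform_regular(n, rho, seed=spec.seed)
    if fam == "random_fill":
        nx, ny, rho = _require(spec, "nx", "ny", "rho")
        return random_fill(nx, ny, rho, seed=spec.seed)
    if fam == "nested_packed":
        (n,) = _require(spec, "n")
        return nested_packed(n)
    if fam == "nested_general":
        nx, ny, rho = _require(spec, "nx", "ny", "rho")
        return nested_general(nx, ny, rho, seed=spec.seed)
    if fam == "modular_isometric":
        m, t = _require(spec, "m", "t")
        return modular_isometric(m, t)
    if fam == "modular_rect":
        m, t, z = _require(spec, "m", "t", "z")
        return modular_rect(m, t, z)
    if fam == "modular_increasing":
        (m,) = _require(spec, "m")
        return modular_increasing(m)
    if fam == "compound_nested":
        m, t = _require(spec, "m", "t")
        return compound_nested(m, t)
    raise AssertionError(fam)


def planted_modules(spec: TopologySpec) -> tuple[np.ndarray, np.ndarray]:
    """Module labels of rows and columns as laid down by the generator.

    Defined for the block-diagonal families only.
    """
    fam = spec.family
    if fam in ("modular_isometric", "compound_nested"):
        m, t = _require(spec, "m", "t")
        labels = np.repeat(np.arange(m), t)
        return labels, labels.copy()
    if fam == "modular_rect":
        m, t, z = _require(spec, "m", "t", "z")
        return np.repeat(np.arange(m), t), np.repeat(np.arange(m), z)
    if fam == "modular_increasing":
        (m,) = _require(spec, "m")
        labels = np.repeat(np.arange(m), np.arange(1, m + 1))
        return labels, labels.copy()
    raise ValueError(f"family {fam!r} has no planted module structure")


def uniform_regular(n: int, rho: float, seed: int | None = None) -> InteractionMatrix:
    """Square binary matrix with all margins equal to k = rho*N.

    Built by overlaying k cyclically shifted diagonals, which fixes every
    row and column sum at k; with a seed, degree-preserving checkerboard
    swaps then shuffle the arrangement.  S depends only on the margins,
    so the shuffle is cosmetic.
    """
    if n < 1:
        raise ValueError(f"N must be >= 1, got {n}")
    k_float = rho * n
    k = _round_half_away(k_float)
    if abs(k_float - k) > 1e-9 or not 1 <= k <= n:
        feasible = ", ".join(f"{i}/{n}" for i in range(1, min(n, 6) + 1))
        raise ValueError(
            f"rho*N = {k_float:g} is not an integer in [1, {n}]; "
            f"feasible rho are multiples of 1/{n} ({feasible}, ...)"
        )
    a = np.zeros((n, n), dtype=np.int64)
    i = np.arange(n)
    for shift in range(k):
        a[i, (i + shift) % n] = 1
    if seed is not None and 0 < k < n:
        from .nullmodels import shuffle_preserving_degrees

        shuffle_preserving_degrees(a, n_swaps=2 * n * k, rng=np.random.default_rng(seed))
    return _labeled(a)


def random_fill(nx: int, ny: int, rho: float, seed: int | None = None) -> InteractionMatrix:
    """Binary matrix with round(rho*NX*NY) cells occupied uniformly at random."""
    if not 0 < rho <= 1:
        raise ValueError(f"occupancy must be in (0, 1], got {rho}")
    count = _round_half_away(rho * nx * ny)
    if count < 1:
        raise ValueError(f"rho={rho:g} fills no cell of a {nx}x{ny} matrix")
    rng = np.random.default_rng(seed)
    flat = rng.choice(nx * ny, size=count, replace=False)
    a = np.zeros(nx * ny, dtype=np.int64)
    a[flat] = 1
    return _labeled(a.reshape(nx, ny))


def nested_packed(n: int) -> InteractionMatrix:
    """Square matrix fully packed above the antidiagonal.

    Sorted by decreasing degree, row i (0-based) carries N - i left-packed
    ones; NM = N(N+1)/2 and the occupancy is (N+1)/2N.
    """
    if n < 2:
        raise ValueError(f"packed nested matrix requires N >= 2, got {n}")
    a = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        a[i, : n - i] = 1
    return _labeled(a)


def _nested_profile(nx: int, ny: int, gamma: float) -> np.ndarray:
    """Row lengths from a power-curve nesting boundary; non-increasing, in [1, NY]."""
    i = np.arange(nx, dtype=float)
    lens = np.ceil(ny * (1.0 - (i / nx) ** gamma)).astype(np.int64)
    return np.clip(lens, 1, ny)


def nested_general(
    nx: int, ny: int, rho: float, seed: int | None = None
) -> InteractionMatrix:
    """Perfectly nested binary matrix at a target occupancy.

    Rows are left-packed with non-increasing lengths, so every row's
    partner set is a subset of every longer row's.  The first row spans
    all columns (no empty column) and every row keeps at least one cell,
    which bounds the feasible occupancy from below.  A power-curve
    boundary is bisected to approach the target cell count, then single
    cells are added or removed (seeded choice among admissible rows)
    until the count is met exactly.
    """
    if nx < 1 or ny < 1:
        raise ValueError("NX and NY must be >= 1")
    target = _round_half_away(rho * nx * ny)
    lo = ny + (nx - 1)
    hi = nx * ny
    if not lo <= target <= hi:
        raise ValueError(
            f"target occupancy {rho:g} infeasible for a {nx}x{ny} nested matrix; "
            f"feasible rho range is [{lo / (nx * ny):.4g}, 1]"
        )
    g_lo, g_hi = 1e-6, 1e6
    for _ in range(200):
        g = math.sqrt(g_lo * g_hi)
        if _nested_profile(nx, ny, g).sum() < target:
            g_lo = g
        else:
            g_hi = g
    lens = _nested_profile(nx, ny, g_hi)
    rng = np.random.default_rng(seed)
    while lens.sum() > target:
        # shrinkable: keeps >= 1 cell and stays non-increasing; first row stays full
        ok = np.flatnonzero(
            (np.arange(nx) > 0)
            & (lens > 1)
            & (lens > np.append(lens[1:], 1))
        )
        lens[rng.choice(ok)] -= 1
    while lens.sum() < target:
        ok = np.flatnonzero((np.arange(nx) > 0) & (lens < np.append(ny, lens[:-1])))
        lens[rng.choice(ok)] += 1
    a = np.zeros((nx, ny), dtype=np.int64)
    for i, ln in enumerate(lens):
        a[i, :ln] = 1
    return _labeled(a)


def modular_isometric(m: int, t: int) -> InteractionMatrix:
    """Block-diagonal matrix of m full t x t modules (N = mt, rho = 1/m)."""
    if m < 1 or t < 1:
        raise ValueError("m and t must be >= 1")
    return _labeled(np.kron(np.eye(m, dtype=np.int64), np.ones((t, t), dtype=np.int64)))


def modular_rect(m: int, t: int, z: int) -> InteractionMatrix:
    """Block-diagonal matrix of m full t x z modules (NX = mt, NY = mz)."""
    if min(m, t, z) < 1:
        raise ValueError("m, t and z must be >= 1")
    return _labeled(np.kron(np.eye(m, dtype=np.int64), np.ones((t, z), dtype=np.int64)))


def modular_increasing(m: int) -> InteractionMatrix:
    """Square diagonal blocks of sides 1, 2, .., m; N = m(m+1)/2."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    n = m * (m + 1) // 2
    a = np.zeros((n, n), dtype=np.int64)
    off = 0
    for side in range(1, m + 1):
        a[off : off + side, off : off + side] = 1
        off += side
    return _labeled(a)


def compound_nested(m: int, t: int) -> InteractionMatrix:
    """m diagonal blocks, each the t x t packed nested pattern.

    Per-module interactions Km = t(t+1)/2; NM = m*Km.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if t < 2:
        raise ValueError(f"nested module requires t >= 2, got {t}")
    block = nested_packed(t).values
    return _labeled(np.kron(np.eye(m, dtype=np.int64), block))
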