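"""Closed-form normalized mutual information for model matrix families.

Each family of the generator module has an exact solution for S and the
occupancy rho, derived from the flat or triangular degree distributions of
the family.  Hyperfactorial-type sums appear in the nested families and
are evaluated directly in log space (log Hyp(n) = sum i*log i), never by
forming the astronomically large Hyp(n) itself.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AnalyticResult",
    "log_hyp",
    "log_hyp_sq",
    "s_uniform",
    "s_nested_packed",
    "s_modular_iso",
    "occupancy_modular",
    "equal_S_condition",
    "s_modular_rect",
    "s_increasing",
    "s_compound",
]


@dataclass(frozen=True)
class AnalyticResult:
    """Closed-form S and occupancy, with intermediates where meaningful."""

    s: float
    rho: float
    hx: float | None = None
    hxy: float | None = None
    nm: int | None = None


def log_hyp(n: int) -> float:
    """log of the hyperfactorial Hyp(n) = prod i^i, i.e. sum_{i=1}^{n} i*log i."""
    if n < 1:
        raise ValueError(f"log_hyp requires n >= 1, got {n}")
    i = np.arange(2, n + 1, dtype=float)
    return float(np.sum(i * np.log(i)))


def log_hyp_sq(n: int) -> float:
    """log of the squared-index hyperfactorial prod i^(i^2): sum i^2*log i."""
    if n < 1:
        raise ValueError(f"log_hyp_sq requires n >= 1, got {n}")
    i = np.arange(2, n + 1, dtype=float)
    return float(np.sum(i * i * np.log(i)))


def s_uniform(nx: int, ny: int, rho: float) -> AnalyticResult:
    """S of a matrix with flat margins and occupancy rho.

    S = log(1/rho) / log(rho*NX*NY); only the product NX*NY enters, so
    matrices of equal total size and occupancy share S regardless of shape.
    """
    if not 0 < rho <= 1:
        raise ValueError(f"occupancy must be in (0, 1], got {rho}")
    nm = rho * nx * ny
    if nm <= 1 + 1e-12:
        raise ValueError(
            f"rho*NX*NY = {nm:g} <= 1: joint entropy vanishes, S undefined"
        )
    s = math.log(1.0 / rho) / math.log(nm)
    return AnalyticResult(s=s, rho=rho, hxy=math.log(nm), nm=round(nm))


def s_nested_packed(n: int) -> AnalyticResult:
    """S of the fully packed nested square matrix (row degrees k_i = i).

    NM = N(N+1)/2 and H(X) = log NM - log Hyp(N)/NM, giving
    S = (2 H(X) - log NM) / log NM.
    """
    if n < 2:
        raise ValueError(f"packed nested matrix requires N >= 2, got {n}")
    nm = n * (n + 1) // 2
    log_nm = math.log(nm)
    hx = log_nm - log_hyp(n) / nm
    s = (2.0 * hx - log_nm) / log_nm
    return AnalyticResult(s=s, rho=(n + 1) / (2 * n), hx=hx, hxy=log_nm, nm=nm)


def s_modular_iso(n: int, t: int) -> AnalyticResult:
    """S of a square matrix of m = N/t full t x t diagonal blocks.

    S = (log N - log t)/(log N + log t); rho = 1/m.
    """
    if t < 1 or n < 1:
        raise ValueError("N and t must be >= 1")
    if n % t:
        raise ValueError(f"module size t={t} must divide N={n}")
    if n * t <= 1:
        raise ValueError("1x1 matrix: S undefined")
    m = n // t
    s = (math.log(n) - math.log(t)) / (math.log(n) + math.log(t))
    return AnalyticResult(s=s, rho=1.0 / m, hx=math.log(n), hxy=math.log(n * t), nm=n * t)


def occupancy_modular(m: int) -> float:
    """Occupancy of the isometric modular model: rho = 1/m."""
    if m < 1:
        raise ValueError(f"module count must be >= 1, got {m}")
    return 1.0 / m


def equal_S_condition(n1: int, t1: int, n2: int, t2: int, rel_tol: float = 1e-9) -> bool:
    """Whether two isometric modular matrices share the same S.

    Two such matrices have equal S iff log N1/log t1 = log N2/log t2,
    i.e. module size and matrix size are in the same power relationship.
    The diagonal class t = 1 (S = 1) matches only itself.
    """
    for n, t in ((n1, t1), (n2, t2)):
        if t < 1 or n < t or n % t:
            raise ValueError(f"invalid isometric spec N={n}, t={t}")
    if t1 == 1 or t2 == 1:
        return t1 == 1 and t2 == 1
    return math.isclose(
        math.log(n1) / math.log(t1), math.log(n2) / math.log(t2), rel_tol=rel_tol
    )


def s_modular_rect(m: int, t: int, z: int) -> AnalyticResult:
    """S of m full t x z diagonal blocks (NX = mt, NY = mz).

    S = log m / log(m*t*z); reduces to the isometric case when t = z.
    """
    if min(m, t, z) < 1:
        raise ValueError("m, t, z must be >= 1")
    if m * t * z <= 1:
        raise ValueError("1x1 matrix: S undefined")
    s = math.log(m) / math.log(m * t * z)
    return AnalyticResult(s=s, rho=1.0 / m, hxy=math.log(m * t * z), nm=m * t * z)


def s_increasing(m: int) -> AnalyticResult:
    """S of the square matrix of m full diagonal blocks of sides 1..m.

    N = m(m+1)/2, NM = m(m+1)(2m+1)/6, rho = 2(2m+1)/(3m(m+1)),
    H(X) = log NM - log Hyp^2(m)/NM and S = (2 H(X) - log NM)/log NM.
    """
    if m < 2:
        raise ValueError(f"increasing-module model requires m >= 2, got {m}")
    n = m * (m + 1) // 2
    nm = m * (m + 1) * (2 * m + 1) // 6
    rho = 2.0 * (2 * m + 1) / (3.0 * m * (m + 1))
    log_nm = math.log(nm)
    hx = log_nm - log_hyp_sq(m) / nm
    s = (2.0 * hx - log_nm) / log_nm
    return AnalyticResult(s=s, rho=rho, hx=hx, hxy=log_nm, nm=nm)


def s_compound(m: int, t: int) -> AnalyticResult:
    """S of m diagonal blocks, each the t x t packed nested pattern.

    Per-module interactions Km = t(t+1)/2, NM = m*Km,
    H(X) = log NM - (m/NM)*log Hyp(t), S = (2 H(X) - log NM)/log NM.
    """
    if m < 1:
        raise ValueError(f"module count must be >= 1, got {m}")
    if t < 2:
        raise ValueError(f"nested module requires t >= 2, got {t}")
    km = t * (t + 1) // 2
    nm = m * km
    n = m * t
    log_nm = math.log(nm)
    hx = log_nm - (m / nm) * log_hyp(t)
    s = (2.0 * hx - log_nm) / log_nm
    return AnalyticResult(s=s, rho=nm / (n * n), hx=hx, hxy=log_nm, nm=nm)
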