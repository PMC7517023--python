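"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use plain-Python loops over the defining
formulas, independent of the vectorized implementations they check.
"""
from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pytest


def slow_entropy(ps) -> float:
    return -sum(p * math.log(p) for p in ps if p > 0)


def slow_decompose(values):
    """(HX, HY, HXY, I, S) straight from the probability definitions."""
    values = [[int(v) for v in row] for row in np.asarray(values)]
    nm = sum(sum(row) for row in values)
    px = [sum(row) / nm for row in values]
    py = [sum(row[j] for row in values) / nm for j in range(len(values[0]))]
    pxy = [v / nm for row in values for v in row]
    hx, hy, hxy = slow_entropy(px), slow_entropy(py), slow_entropy(pxy)
    mi = hx + hy - hxy
    return hx, hy, hxy, mi, mi / hxy


def iter_tables(kx, ky):
    """All non-negative integer tables with the given margins (tiny cases)."""
    kx, ky = list(kx), list(ky)

    def rows(remaining_cols, margins):
        if not margins:
            if all(c == 0 for c in remaining_cols):
                yield []
            return
        k, rest = margins[0], margins[1:]
        for row in compositions(k, remaining_cols):
            left = [c - r for c, r in zip(remaining_cols, row)]
            for tail in rows(left, rest):
                yield [row] + tail

    def compositions(total, caps):
        if len(caps) == 1:
            if total <= caps[0]:
                yield [total]
            return
        for first in range(min(total, caps[0]) + 1):
            for rest in compositions(total - first, caps[1:]):
                yield [first] + rest

    yield from rows(ky, kx)


def exhaustive_max_mi(kx, ky) -> float:
    """Max I(X;Y) over every table with the given margins (exact, tiny only)."""
    best = -math.inf
    for table in iter_tables(kx, ky):
        _, _, _, mi, _ = slow_decompose(table)
        best = max(best, mi)
    return best


def brute_nodf(values) -> float:
    """NODF by explicit pair enumeration."""
    a = np.asarray(values)
    total, n_pairs = 0.0, 0
    for mat in (a, a.T):
        deg = [int(row.sum()) for row in mat]
        for i, j in combinations(range(len(deg)), 2):
            n_pairs += 1
            if deg[i] == deg[j] or min(deg[i], deg[j]) == 0:
                continue
            shared = int((mat[i] & mat[j]).sum())
            total += 100.0 * shared / min(deg[i], deg[j])
    return total / n_pairs


def random_count_matrix(rng, max_side=8, max_count=5, binary=False):
    """A random non-degenerate interaction matrix as an int array."""
    while True:
        nx = rng.integers(1, max_side + 1)
        ny = rng.integers(1, max_side + 1)
        if binary:
            a = (rng.random((nx, ny)) < rng.uniform(0.2, 0.9)).astype(np.int64)
        else:
            a = rng.integers(0, max_count + 1, size=(nx, ny))
        if np.count_nonzero(a) >= 2:
            return a


@pytest.fixture
def rng():
    return np.random.default_rng(20200528)
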