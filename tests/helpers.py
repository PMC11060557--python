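"""Independent brute-force oracles used to check the statistical kernels.

Everything here is deliberately naive — enumeration and first-principles
formulas only — and shares no code path with the package implementation.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np


def hypergeom_tail_enum(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeom(N, K, n) by exact rational enumeration."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for kk in range(max(k, 0), min(K, n) + 1):
        acc += Fraction(math.comb(K, kk) * math.comb(N - K, n - kk), total)
    return float(acc)


def bh_stepup(pvals) -> np.ndarray:
    """Naive Benjamini–Hochberg step-up adjusted p-values.

    Computed in exact rational arithmetic, so the only deviation from any
    correct float implementation is that implementation's rounding.
    """
    p = [Fraction(v) for v in np.asarray(pvals, dtype=float)]
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [Fraction(0)] * m
    running = Fraction(1)
    for rank_from_end, idx in enumerate(reversed(order)):
        i = m - rank_from_end  # 1-based rank of this p-value
        running = min(running, p[idx] * m / i)
        adj[idx] = running
    return np.array([float(v) for v in adj])


def wilcoxon_exact_two_sided(x, y) -> float:
    """Exact permutation two-sided p for the rank-sum (Mann-Whitney U) test.

    Enumerates every assignment of the pooled values into the two groups and
    uses the doubled smaller tail of the U distribution, clipped at 1 — the
    convention of the exact rank-sum test for tie-free data.
    """
    x, y = list(x), list(y)
    pooled = np.asarray(x + y, dtype=float)
    n1, n2 = len(x), len(y)
    ranks = _average_ranks(pooled)
    u_obs = float(np.sum(ranks[:n1])) - n1 * (n1 + 1) / 2.0
    ge = le = total = 0
    for idx in combinations(range(n1 + n2), n1):
        u = float(np.sum(ranks[list(idx)])) - n1 * (n1 + 1) / 2.0
        total += 1
        if u >= u_obs - 1e-12:
            ge += 1
        if u <= u_obs + 1e-12:
            le += 1
    return min(1.0, 2.0 * min(ge, le) / total)


def _average_ranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def rs_from_definitions(positions, n: int, L: int):
    """(E, J, RS) recomputed from the printed definitions, plain Python."""
    assert len(positions) == n and n >= 1
    sq = 0.0
    matched = 0
    for i, p in enumerate(positions, start=1):
        if p is None:
            sq += (L + 1) ** 2
        else:
            matched += 1
            sq += (i - p) ** 2
    e = math.sqrt(sq)
    j = matched / n
    rs = e / j if j > 0 else e / 1e-6
    return e, j, rs


def random_match_instance(rng: np.random.Generator, max_n: int = 6, max_L: int = 15):
    """A random (positions, n, L) triple with unique in-range positions."""
    n = int(rng.integers(1, max_n + 1))
    L = int(rng.integers(0, max_L + 1))
    n_matched = int(rng.integers(0, min(n, L) + 1))
    pos = rng.choice(L, size=n_matched, replace=False) + 1 if n_matched else []
    positions = [None] * n
    for slot, p in zip(rng.choice(n, size=n_matched, replace=False), pos):
        positions[int(slot)] = int(p)
    return positions, n, L


def random_network_pair(rng: np.random.Generator, n_types: int = 4):
    """Two positive interaction-count matrices over the same cell types."""
    names = tuple(f"T{i}" for i in range(n_types))
    ctl = rng.integers(1, 20, size=(n_types, n_types))
    dis = rng.integers(1, 20, size=(n_types, n_types))
    return names, ctl, dis
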