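"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most transparent route
(quadratic DP, exhaustive enumeration) and share no code with the package
paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Align import substitution_matrices
from scipy.stats import hypergeom

NEG = float("-inf")


def _matrix(name: str = "BLOSUM62"):
    m = substitution_matrices.load(name)
    return lambda a, b: float(m[a, b])


def gotoh_global_score(x: str, y: str, open_gap: int = 11, extend_gap: int = 1,
                       matrix_name: str = "BLOSUM62") -> float:
    """Affine-gap global alignment score, end gaps penalized (Gotoh DP)."""
    s = _matrix(matrix_name)
    first, ext = -(open_gap + extend_gap), -extend_gap
    n, m = len(x), len(y)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in y (x consumed)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in x (y consumed)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = first + ext * (i - 1)
    for j in range(1, m + 1):
        Iy[0][j] = first + ext * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best_prev = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = best_prev + s(x[i - 1], y[j - 1])
            Ix[i][j] = max(M[i - 1][j] + first, Ix[i - 1][j] + ext, Iy[i - 1][j] + first)
            Iy[i][j] = max(M[i][j - 1] + first, Iy[i][j - 1] + ext, Ix[i][j - 1] + first)
    return max(M[n][m], Ix[n][m], Iy[n][m])


def gotoh_local_score(x: str, y: str, open_gap: int = 11, extend_gap: int = 1,
                      matrix_name: str = "BLOSUM62") -> float:
    """Affine-gap Smith-Waterman score (Gotoh DP with zero floor)."""
    s = _matrix(matrix_name)
    first, ext = -(open_gap + extend_gap), -extend_gap
    n, m = len(x), len(y)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            prev = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1], 0.0)
            M[i][j] = max(prev + s(x[i - 1], y[j - 1]), 0.0)
            Ix[i][j] = max(M[i - 1][j] + first, Ix[i - 1][j] + ext)
            Iy[i][j] = max(M[i][j - 1] + first, Iy[i][j - 1] + ext)
            best = max(best, M[i][j])
    return best


def brute_force_contacts(chain_a, chain_b, contact_cutoff: float):
    """All-atom-pair contact scan over two Residue lists."""
    pairs = set()
    for ra in chain_a:
        if ra.aa == "X":
            continue
        for rb in chain_b:
            if rb.aa == "X":
                continue
            for _, ea, xa, ya, za in ra.atoms:
                if ea == "H":
                    continue
                for _, eb, xb, yb, zb in rb.atoms:
                    if eb == "H":
                        continue
                    d = math.dist((xa, ya, za), (xb, yb, zb))
                    if d <= contact_cutoff:
                        pairs.add((ra.seq_index, rb.seq_index))
    return pairs


def fisher_enumeration(a: int, b: int, c: int, d: int, sided: str = "two") -> float:
    """Exact Fisher p by enumerating all tables with the observed margins."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    xs = np.arange(lo, hi + 1)
    p = hypergeom.pmf(xs, n, r1, c1)
    p_obs = p[a - lo]
    if sided == "two":
        return float(p[p <= p_obs * (1 + 1e-7)].sum())
    if sided == "greater":
        return float(p[xs >= a].sum())
    raise ValueError(sided)


def mwu_enumeration(x, y, sided: str = "two") -> tuple[float, float]:
    """Exact Mann-Whitney U p by full enumeration of group assignments."""
    x, y = list(x), list(y)
    pooled = x + y
    nx = len(x)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}  # no ties assumed

    def u_of(idx):
        rx = sum(ranks[pooled[i]] for i in idx)
        return rx - nx * (nx + 1) / 2

    u_obs = sum(ranks[v] for v in x) - nx * (nx + 1) / 2
    us = [u_of(idx) for idx in itertools.combinations(range(len(pooled)), nx)]
    total = len(us)
    n_other = len(y)
    if sided == "greater":
        p = sum(1 for u in us if u >= u_obs) / total
    elif sided == "less":
        p = sum(1 for u in us if u <= u_obs) / total
    else:
        mean_u = nx * n_other / 2
        dev = abs(u_obs - mean_u)
        p = sum(1 for u in us if abs(u - mean_u) >= dev - 1e-12) / total
    return u_obs, min(1.0, p)
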