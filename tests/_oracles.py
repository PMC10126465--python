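"""Independent brute-force oracles used by the test suite.

These deliberately avoid the production code paths: the breakpoint
oracle builds the model basis vectors explicitly and enumerates every
ordered triple; the alignment oracle is a from-scratch dynamic program
over the three edit moves (equivalent to exhaustive enumeration of all
global alignments with linear gap costs).
"""

from __future__ import annotations

import math

import numpy as np


def _phi(T: int, b1: int, b2: int, b3: int):
    t = np.arange(T, dtype=float)
    phi0 = np.where(t <= b1, 1.0 - t / b1, 0.0)
    phi1 = np.where(
        t <= b1, t / b1, np.where(t <= b2, (b2 - t) / (b2 - b1), 0.0)
    )
    phi2 = np.where(
        (t > b1) & (t <= b2),
        (t - b1) / (b2 - b1),
        np.where((t > b2) & (t <= b3), (b3 - t) / (b3 - b2), 0.0),
    )
    return phi0, phi1, phi2


def _solve_values(y, phi0, phi1, phi2, alpha):
    """Exact 2-variable constrained QP: interior solution or the best
    point on one of the three constraint faces (v1<=1, v2>=0,
    v2 <= (1+alpha) v1 - alpha)."""
    r = y - phi0
    A11 = float(phi1 @ phi1)
    A12 = float(phi1 @ phi2)
    A22 = float(phi2 @ phi2)
    c1 = float(phi1 @ r)
    c2 = float(phi2 @ r)
    C = float(r @ r)
    beta = 1.0 + alpha
    lo_v1 = alpha / beta
    eps = 1e-9

    def q(v1, v2):
        return C - 2.0 * (c1 * v1 + c2 * v2) + A11 * v1**2 + 2.0 * A12 * v1 * v2 + A22 * v2**2

    cands = []
    det = A11 * A22 - A12 * A12
    if abs(det) > 1e-300:
        u1 = (A22 * c1 - A12 * c2) / det
        u2 = (A11 * c2 - A12 * c1) / det
        if u1 <= 1.0 + eps and u2 >= -eps and u2 <= beta * u1 - alpha + eps:
            cands.append((u1, u2))
    cands.append((1.0, min(max((c2 - A12) / A22, 0.0), 1.0)))
    cands.append((min(max(c1 / A11, lo_v1), 1.0), 0.0))
    denom = A11 + 2.0 * A12 * beta + A22 * beta**2
    if abs(denom) > 1e-300:
        v1 = min(max((c1 + beta * c2 + A12 * alpha + A22 * beta * alpha) / denom, lo_v1), 1.0)
        cands.append((v1, beta * v1 - alpha))
    best = min(cands, key=lambda v: q(*v))
    return best[0], best[1], q(*best)


def brute_force_breakpoints(y: np.ndarray, slope_factor: float = 3.0):
    """Exhaustive enumeration over all ordered breakpoint triples.

    Returns (b1, b2, b3, v1, v2, sse); ties in SSE resolve to the
    lexicographically smallest triple.
    """
    T = y.size
    best_sse = math.inf
    best = None
    for b1 in range(1, T - 2):
        for b2 in range(b1 + 1, T - 1):
            alpha = slope_factor * (b2 - b1) / b1
            for b3 in range(b2 + 1, T):
                phi0, phi1, phi2 = _phi(T, b1, b2, b3)
                v1, v2, sse = _solve_values(y, phi0, phi1, phi2, alpha)
                if sse < best_sse:
                    best_sse = sse
                    best = (b1, b2, b3, v1, v2, sse)
    return best


def nw_linear_score(a: str, b: str, match: float, mismatch: float, gap: float) -> float:
    """Optimal global alignment score, linear gap cost per gap symbol,
    end gaps penalized (Needleman–Wunsch over all alignments)."""
    n, m = len(a), len(b)
    prev = [-gap * j for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [-gap * i] + [0.0] * m
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            cur[j] = max(prev[j - 1] + s, prev[j] - gap, cur[j - 1] - gap)
        prev = cur
    return prev[m]


def enumerate_alignment_score(a: str, b: str, match: float, mismatch: float, gap: float) -> float:
    """Literal recursive enumeration of all global alignments (tiny
    inputs only); used to cross-check the DP above on a few pairs."""
    if not a and not b:
        return 0.0
    opts = []
    if a and b:
        s = match if a[0] == b[0] else mismatch
        opts.append(s + enumerate_alignment_score(a[1:], b[1:], match, mismatch, gap))
    if a:
        opts.append(-gap + enumerate_alignment_score(a[1:], b, match, mismatch, gap))
    if b:
        opts.append(-gap + enumerate_alignment_score(a, b[1:], match, mismatch, gap))
    return max(opts)
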