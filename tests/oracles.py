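"""Independent brute-force oracles used by the test suite.

These deliberately avoid the production code paths: the dissimilarity oracle
minimizes over a fine interpolation grid, and the scanline oracle searches
the legal-assignment graph directly (memoized shortest chain), with a
separate straight-line cost evaluator for checking returned assignments.
"""
from functools import lru_cache
from itertools import combinations

import numpy as np


def brute_force_dissimilarity(left_row, right_row, xl, xr, step=1e-4):
    """Fine-grid minimization of the sampling-insensitive dissimilarity."""
    L = np.asarray(left_row, float)
    R = np.asarray(right_row, float)

    def one_sided(a, other, x_other):
        ts = np.arange(x_other - 0.5, x_other + 0.5 + step, step)
        interp = np.interp(ts, np.arange(other.size), other)  # clamped ends
        return np.abs(a - interp).min()

    return min(one_sided(L[xl], R, xr), one_sided(R[xr], L, xl))


def exact_dissimilarity(left_row, right_row, xl, xr):
    """Exact sampling-insensitive dissimilarity via segment interval logic.

    For each half-pixel segment of the piecewise-linear interpolant the
    minimum of |a - lerp| is 0 if a lies between the endpoint values, else
    the distance to the nearer endpoint.
    """
    L = np.asarray(left_row, float)
    R = np.asarray(right_row, float)

    def seg_min(a, y0, y1):
        lo, hi = min(y0, y1), max(y0, y1)
        if lo <= a <= hi:
            return 0.0
        return min(abs(a - y0), abs(a - y1))

    def one_sided(a, other, x):
        n = other.size
        v = other[x]
        vm = 0.5 * (v + other[max(x - 1, 0)])
        vp = 0.5 * (v + other[min(x + 1, n - 1)])
        return min(seg_min(a, vm, v), seg_min(a, v, vp))

    return min(one_sided(L[xl], R, xr), one_sided(R[xr], L, xl))


def assignment_cost(left_row, right_row, matches, kocc, kr):
    """Cost of an explicit match sequence under the scanline objective.

    ``matches`` is a list of (left_index, right_index) pairs, strictly
    increasing in both coordinates, consecutive pairs contiguous in at least
    one coordinate; each non-contiguous transition is one occlusion.
    """
    total = 0.0
    for k, (i, r) in enumerate(matches):
        total += exact_dissimilarity(left_row, right_row, i, r) - kr
        if k > 0:
            pi, pr = matches[k - 1]
            assert i > pi and r > pr, "ordering violated"
            assert i == pi + 1 or r == pr + 1, "two-sided gap is illegal"
            if i != pi + 1 or r != pr + 1:
                total += kocc
    return total


def optimal_scanline_cost(left_row, right_row, dmax, kocc, kr, dmin=0):
    """Exhaustive optimum over all legal match/occlusion assignments.

    Memoized search over the transition graph of match pairs; the empty
    assignment (cost 0) is always admissible.
    """
    L = np.asarray(left_row, float)
    R = np.asarray(right_row, float)
    W = L.size
    dis = {}
    for i in range(W):
        for r in range(max(i - dmax, 0), i - dmin + 1):
            dis[(i, r)] = exact_dissimilarity(L, R, i, r)

    @lru_cache(maxsize=None)
    def best_from(i, r):
        """Min cost of the chain starting with match (i, r)."""
        here = dis[(i, r)] - kr
        best = 0.0  # stop matching
        # contiguous
        if (i + 1, r + 1) in dis:
            best = min(best, best_from(i + 1, r + 1))
        # gap in right image: next left pixel, skip right pixels
        for r2 in range(r + 2, i + 2):
            if (i + 1, r2) in dis:
                best = min(best, kocc + best_from(i + 1, r2))
        # gap in left image: next right pixel, skip left pixels
        for i2 in range(i + 2, r + 1 + dmax + 1):
            if (i2, r + 1) in dis:
                best = min(best, kocc + best_from(i2, r + 1))
        return here + best

    best = 0.0
    for (i, r) in dis:
        best = min(best, best_from(i, r))
    best_from.cache_clear()
    return best


def mann_whitney_enumeration(a, b):
    """Exact two-sided Mann-Whitney p by full enumeration of group splits."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1 = len(a)

    def u_stat(x, y):
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)

    u_obs = u_stat(a, b)
    us = []
    idx = range(len(pooled))
    for comb in combinations(idx, n1):
        sel = np.zeros(len(pooled), bool)
        sel[list(comb)] = True
        us.append(u_stat(pooled[sel], pooled[~sel]))
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))
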