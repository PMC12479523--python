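"""Brute-force reference implementations used only to check the package.

Everything here is deliberately naive — explicit loops, exact rational
arithmetic where possible — and shares no code with the implementation
under test.
"""

from fractions import Fraction
from math import comb

import numpy as np


def midrank(values):
    """Average ranks with midranks for ties, by explicit tie-run averaging."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1  # ranks are 1-based
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return np.array(ranks)


def spearman_oracle(x, y):
    """Midrank both vectors, then plain Pearson correlation."""
    rx, ry = midrank(x), midrank(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def partial_spearman_oracle(x, y, Z):
    """Rank everything, regress covariates out of both, correlate residuals."""
    rx, ry = midrank(x), midrank(y)
    Z = np.atleast_2d(np.asarray(Z, float).T).T
    rz = np.column_stack([midrank(Z[:, j]) for j in range(Z.shape[1])])
    design = np.column_stack([np.ones(len(rx)), rz])
    ex = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    ey = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    return float(np.corrcoef(ex, ey)[0, 1])


def bh_oracle(p):
    """Step-up adjusted p-values by explicit double loop over order stats."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for pos_i, idx in enumerate(order):
        best = min(
            p[order[pos_j]] * m / (pos_j + 1) for pos_j in range(pos_i, m)
        )
        q[idx] = min(best, 1.0)
    return np.array(q)


def bh_oracle_long(p):
    """Step-up oracle with an explicit outer loop over order statistics,
    vectorized inner minimum so long vectors stay tractable."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    ranks = np.arange(1, m + 1)
    q = np.empty(m)
    scaled = p_sorted * m / ranks
    for pos in range(m):
        q[order[pos]] = min(scaled[pos:].min(), 1.0)
    return q


def hypergeom_pmf_exact(k, M, K, n):
    """Exact rational P(X = k) for the 2x2 table's hypergeometric."""
    return Fraction(comb(K, k) * comb(M - K, n - k), comb(M, n))


def fisher_oracle(n_a, n_b, k, M, alternative):
    """Exact Fisher p by full enumeration of the overlap support."""
    k_min = max(0, n_a + n_b - M)
    k_max = min(n_a, n_b)
    masses = {kk: hypergeom_pmf_exact(kk, M, n_a, n_b)
              for kk in range(k_min, k_max + 1)}
    if alternative == "greater":
        total = sum(masses[kk] for kk in range(k, k_max + 1))
    else:
        cutoff = masses[k] * Fraction(10_000_001, 10_000_000)  # 1 + 1e-7
        total = sum(m for m in masses.values() if m <= cutoff)
    return float(min(total, Fraction(1)))


def complete_linkage_oracle(points):
    """Complete linkage by recomputing max pairwise distances from scratch
    at every step. Returns the sorted list of merge heights."""
    points = np.asarray(points, float)
    clusters = [{i} for i in range(len(points))]
    heights = []
    while len(clusters) > 1:
        best = None
        best_d = np.inf
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(
                    float(np.linalg.norm(points[a] - points[b]))
                    for a in clusters[i]
                    for b in clusters[j]
                )
                if d < best_d:
                    best_d = d
                    best = (i, j)
        i, j = best
        heights.append(best_d)
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
    return sorted(heights)
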