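"""Independent brute-force oracles used by the test suite.

These deliberately use explicit Python loops and textbook formulas, not
the package's vectorized implementations, so agreement between the two is
a meaningful check.
"""

from __future__ import annotations

import numpy as np


def grey_degree_loops(reference, comparatives, rho):
    """Loop-based grey relational degrees: deviations, extremes, xi, GRD."""
    ref = list(reference)
    n = len(ref)
    m = len(comparatives)
    dev = [[abs(ref[k] - comparatives[i][k]) for k in range(n)] for i in range(m)]
    flat = [dev[i][k] for i in range(m) for k in range(n)]
    d_min, d_max = min(flat), max(flat)
    grd = []
    for i in range(m):
        total = 0.0
        for k in range(n):
            if d_max == 0:
                xi = 1.0
            else:
                xi = (d_min + rho * d_max) / (dev[i][k] + rho * d_max)
            total += xi
        grd.append(total / n)
    return np.array(grd)


def cd2_loops(levels):
    """Double-sum centered L2 discrepancy, straight from the formula."""
    levels = np.asarray(levels, dtype=float)
    n, s = levels.shape
    u = (levels - 0.5) / n
    term1 = (13.0 / 12.0) ** s
    term2 = 0.0
    for i in range(n):
        prod = 1.0
        for j in range(s):
            a = abs(u[i, j] - 0.5)
            prod *= 1.0 + 0.5 * a - 0.5 * a * a
        term2 += prod
    term2 *= 2.0 / n
    term3 = 0.0
    for i in range(n):
        for k in range(n):
            prod = 1.0
            for j in range(s):
                ai = abs(u[i, j] - 0.5)
                ak = abs(u[k, j] - 0.5)
                prod *= 1.0 + 0.5 * ai + 0.5 * ak - 0.5 * abs(u[i, j] - u[k, j])
            term3 += prod
    term3 /= n * n
    return float(np.sqrt(max(term1 - term2 + term3, 0.0)))


def random_latin(n, s, rng):
    """A random U-type layout: every column a permutation of 1..n."""
    return np.column_stack([rng.permutation(n) + 1 for _ in range(s)])
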