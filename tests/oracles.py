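"""Independent brute-force oracles used only by the test suite."""

import math

import numpy as np


def fisher_p_enumeration(a, b, c, d, alternative="two-sided"):
    """Exact Fisher p by explicit enumeration of all tables with the
    observed margins, using binomial coefficients only."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = math.comb(n, c1)
    probs = {aa: math.comb(r1, aa) * math.comb(r2, c1 - aa) / denom for aa in range(lo, hi + 1)}
    p_obs = probs[a]
    if alternative == "two-sided":
        return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))
    if alternative == "less":
        return sum(p for aa, p in probs.items() if aa <= a)
    if alternative == "greater":
        return sum(p for aa, p in probs.items() if aa >= a)
    raise ValueError(alternative)


def kendall_tau_b_pairs(x, y):
    """Tau-b by O(n^2) pair counting with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    denom = math.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))
    if denom == 0:
        return float("nan")
    return (conc - disc) / denom


def _tie_term(v):
    _, counts = np.unique(v, return_counts=True)
    return sum(c * (c - 1) / 2 for c in counts)


def bh_definitional(p_values):
    """Step-up BH straight from the definition: adjusted p of the i-th
    order statistic is min over j >= i of m * p_(j) / j, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        adj_sorted[rank - 1] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def hypergeom_tail_enumeration(overlap, n_universe, n_a, n_b):
    """P(X >= overlap) for the overlap of a random size-n_b subset with a
    fixed size-n_a subset of the universe, by direct summation."""
    denom = math.comb(n_universe, n_b)
    lo = max(0, n_a + n_b - n_universe)
    hi = min(n_a, n_b)
    return sum(
        math.comb(n_a, k) * math.comb(n_universe - n_a, n_b - k) / denom
        for k in range(max(overlap, lo), hi + 1)
    )
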