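"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's vectorised code paths: statistics
are recomputed with explicit per-variant loops, permutation p-values by
exhaustive enumeration of label assignments, the I-value by its falling-
factorial product, and Fisher's exact p by hypergeometric enumeration.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

MISSING = -1


def slow_burden_stat(geno: np.ndarray, case_mask: np.ndarray) -> float:
    """Cumulative case allele count over case-exclusive variants."""
    total = 0
    for j in range(geno.shape[1]):
        y_case = y_ctrl = 0
        for i in range(geno.shape[0]):
            g = geno[i, j]
            if g > 0:
                if case_mask[i]:
                    y_case += int(g)
                else:
                    y_ctrl += int(g)
        if y_case > 0 and y_ctrl == 0:
            total += y_case
    return float(total)


def slow_calpha_stat(geno: np.ndarray, case_mask: np.ndarray) -> float:
    t = 0.0
    any_var = False
    for j in range(geno.shape[1]):
        y = n = 0
        n_case_g = n_ctrl_g = 0
        for i in range(geno.shape[0]):
            g = geno[i, j]
            if g != MISSING:
                if case_mask[i]:
                    n_case_g += 1
                else:
                    n_ctrl_g += 1
            if g > 0:
                n += int(g)
                if case_mask[i]:
                    y += int(g)
        if n >= 1:
            any_var = True
            p0 = n_case_g / (n_case_g + n_ctrl_g)
            t += (y - n * p0) ** 2 - n * p0 * (1 - p0)
    if not any_var:
        raise ValueError("no variants with copies")
    return t


def exhaustive_permutation_p(geno: np.ndarray, observed_mask: np.ndarray,
                             stat_fn) -> float:
    """Upper-tail p over every assignment of the case labels."""
    n = geno.shape[0]
    n_case = int(observed_mask.sum())
    obs = stat_fn(geno, observed_mask)
    hits = total = 0
    for comb in itertools.combinations(range(n), n_case):
        mask = np.zeros(n, dtype=bool)
        mask[list(comb)] = True
        total += 1
        if stat_fn(geno, mask) >= obs - 1e-9:
            hits += 1
    return hits / total


def i_value_product(c: int, n_case: int, n_total: int) -> float:
    """prod_{j<c} (n_case - j) / (n_total - j); 0 carriers -> 1."""
    out = 1.0
    for j in range(c):
        out *= (n_case - j) / (n_total - j)
    return out


def i_value_enumeration(c: int, n_case: int, n_total: int) -> float:
    """Probability that all c carriers land among the cases, by counting
    label assignments directly (feasible for small n_total)."""
    hits = total = 0
    for comb in itertools.combinations(range(n_total), n_case):
        total += 1
        if set(range(c)) <= set(comb):
            hits += 1
    return hits / total


def fisher_p_enumeration(table) -> float:
    """Two-sided Fisher p by summing hypergeometric probabilities of all
    same-margin tables no more likely than the observed one."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))
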