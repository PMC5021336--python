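"""Independent reference implementations used only by the tests.

These deliberately avoid the code paths they check: the Fisher oracle
enumerates the hypergeometric support with exact integer binomials, and
the BH oracle is a plain sort-based step-up.
"""

from fractions import Fraction
from math import comb

import numpy as np


def fisher_two_sided_exact(m_a: int, u_a: int, m_b: int, u_b: int) -> float:
    """Two-sided Fisher p by full enumeration with exact rationals.

    Sums P(k) over the hypergeometric support for every table no more
    likely than the observed one (relative tolerance 1e-7, the standard
    two-sided rule).
    """
    n_a, n_b = m_a + u_a, m_b + u_b
    k_meth, n_tot = m_a + m_b, m_a + u_a + m_b + u_b
    if n_tot == 0:
        return 1.0
    denom = comb(n_tot, k_meth)
    lo = max(0, k_meth - n_b)
    hi = min(k_meth, n_a)
    weights = {k: comb(n_a, k) * comb(n_b, k_meth - k) for k in range(lo, hi + 1)}
    obs = weights[m_a]
    cutoff = Fraction(obs) * (Fraction(10**7 + 1, 10**7))
    total = sum(w for w in weights.values() if w <= cutoff)
    return float(min(Fraction(total, denom), Fraction(1)))


def bh_step_up(p_values) -> np.ndarray:
    """Sort-based Benjamini-Hochberg step-up with monotonicity, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(adjusted[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def interval_overlap_bp(set_x, set_y) -> int:
    """Total overlapped base pairs between two interval lists (1-based incl.)."""
    total = 0
    for s1, e1 in set_x:
        for s2, e2 in set_y:
            total += max(0, min(e1, e2) - max(s1, s2) + 1)
    return total


def total_bp(intervals) -> int:
    return sum(e - s + 1 for s, e in intervals)
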