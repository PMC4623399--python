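"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: direct summation in
80-bit extended precision for the conditional-test tails, brute-force
definitions for BH and the hypergeometric tail, closed forms for the
Student-t CDF at small df, and subset enumeration for the exact
rank-sum null.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

LD = np.longdouble


def ac_terms_longdouble(x: int, ratio: float, k_max: int) -> np.ndarray:
    """p(i|x) for i = 0..k_max by direct multiplicative recurrence."""
    r = LD(ratio)
    one = LD(1)
    t = np.empty(k_max + 1, dtype=np.longdouble)
    t[0] = (one / (one + r)) ** (LD(x) + 1)
    i = np.arange(1, k_max + 1, dtype=np.longdouble)
    factors = r * (LD(x) + i) / (i * (one + r))
    t[1:] = t[0] * np.cumprod(factors)
    return t


def ac_two_sided_oracle(x: int, y: int, ratio: float) -> float:
    """Two-sided doubled-tail p by extended-precision direct summation."""
    k_max = 4 * max(x, y, 1) + 400
    t = ac_terms_longdouble(x, ratio, k_max)
    lower = t[: y + 1].sum()
    if lower <= LD(0.5):
        p = 2 * lower
    else:
        upper = t[y:][::-1].sum()  # backward sum: small terms first
        p = 2 * upper
    return float(min(p, LD(1)))


def bh_bruteforce(pvalues) -> np.ndarray:
    """BH step-up q-values straight from the definition."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    for j in range(m - 2, -1, -1):
        q_sorted[j] = min(q_sorted[j], q_sorted[j + 1])
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def hypergeom_upper_tail(k: int, m_total: int, n_de: int, k_cat: int) -> float:
    """P(X >= k) for X hypergeometric, by exact enumeration with math.comb."""
    denom = math.comb(m_total, n_de)
    total = 0
    for j in range(k, min(n_de, k_cat) + 1):
        total += math.comb(k_cat, j) * math.comb(m_total - k_cat, n_de - j)
    return total / denom


def student_t_cdf_df3(t: float) -> float:
    """Closed-form Student-t CDF at 3 degrees of freedom."""
    z = t / math.sqrt(3.0)
    return 0.5 + (z / (1.0 + z * z) + math.atan(z)) / math.pi


def student_t_cdf_df4(t: float) -> float:
    """Closed-form Student-t CDF at 4 degrees of freedom."""
    s = t / math.sqrt(4.0 + t * t)
    return 0.5 + 0.75 * s - 0.25 * s**3


def rank_sum_exact_two_sided(a, b) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all group splits.

    Matches the doubled-smaller-tail convention: 2*min(P(U<=u), P(U>=u))
    over the exact permutation null, clipped to 1.
    """
    a = list(a)
    b = list(b)
    pooled = a + b
    n1 = len(a)
    ranks = _rankdata(pooled)
    u_obs = sum(ranks[: n1]) - n1 * (n1 + 1) / 2.0
    idx = range(len(pooled))
    us = []
    for comb in combinations(idx, n1):
        u = sum(ranks[i] for i in comb) - n1 * (n1 + 1) / 2.0
        us.append(u)
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _rankdata(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks
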