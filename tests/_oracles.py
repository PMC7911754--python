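"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected values through different code paths
(exact rational arithmetic, exhaustive scans) than the implementation.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def oracle_single_split(x: np.ndarray, min_width: int = 2) -> tuple[int, int]:
    """Exhaustive scan over all circular (i, j) split pairs maximising the
    mean-difference statistic; returns the best (i, j)."""
    n = x.size
    prefix = np.concatenate([[0.0], np.cumsum(x)])
    total = prefix[-1]
    best_t, best = -1.0, (0, 0)
    for i in range(n):
        j = np.arange(i + 1, n + 1 if i > 0 else n)
        k = j - i
        ok = (k >= min_width) & (n - k >= min_width)
        if not ok.any():
            continue
        j, k = j[ok], k[ok]
        s = prefix[j] - prefix[i]
        t = np.abs(s / k - (total - s) / (n - k)) / np.sqrt(1.0 / k + 1.0 / (n - k))
        a = int(np.argmax(t))
        if t[a] > best_t:
            best_t, best = float(t[a]), (i, int(j[a]))
    return best


def exact_fisher_two_sided(table) -> Fraction:
    """Two-sided Fisher p as an exact rational, by enumerating every 2x2
    table with the observed margins and summing the probabilities of those no
    more likely than the observed one."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    probs = {}
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[k] = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
    p_obs = probs[a]
    return sum((p for p in probs.values() if p <= p_obs), Fraction(0))


def exact_hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact rational."""
    denom = comb(N, n)
    total = Fraction(0)
    for x in range(k, min(K, n) + 1):
        total += Fraction(comb(K, x) * comb(N - K, n - x), denom)
    return total
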