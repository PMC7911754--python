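"""Numba kernels for circular binary segmentation.

The split statistic for an arc (i, j) of a segment of n bins is the absolute
difference between the arc mean and the complement mean, scaled by
sqrt(1/k + 1/(n-k)) with k = j - i.  The data variance is a constant under
permutation of bin order, so it is omitted: the permutation test is identical
and the statistic is cheaper.  The permutation loop aborts early only once the
exceedance count already guarantees p >= alpha (the non-significant
direction), which cannot alter any accept/reject decision.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def _max_stat(x: np.ndarray, min_width: int):
    n = x.size
    prefix = np.empty(n + 1)
    prefix[0] = 0.0
    for i in range(n):
        prefix[i + 1] = prefix[i] + x[i]
    total = prefix[n]
    best = -1.0
    bi = 0
    bj = 0
    for i in range(n):
        jmax = n if i > 0 else n - 1  # k == n would leave an empty complement
        for j in range(i + 1, jmax + 1):
            k = j - i
            if k < min_width or n - k < min_width:
                continue
            s = prefix[j] - prefix[i]
            d = s / k - (total - s) / (n - k)
            t = abs(d) / np.sqrt(1.0 / k + 1.0 / (n - k))
            if t > best:
                best = t
                bi = i
                bj = j
    return best, bi, bj


@njit(cache=True, fastmath=True)
def _max_stat_value(x: np.ndarray, min_width: int) -> float:
    t, _, _ = _max_stat(x, min_width)
    return t


@njit(cache=True)
def _perm_pvalue(
    x: np.ndarray, t_obs: float, n_perm: int, alpha: float, min_width: int, seed: int
) -> float:
    np.random.seed(seed)
    y = x.copy()
    n = y.size
    # smallest exceedance count that already implies (exceed+1)/(n_perm+1) >= alpha
    thresh = int(np.ceil(alpha * (n_perm + 1) - 1.0 - 1e-12))
    if thresh < 1:
        thresh = 1
    exceed = 0
    for _ in range(n_perm):
        for i in range(n - 1, 0, -1):  # Fisher-Yates shuffle
            j = np.random.randint(0, i + 1)
            tmp = y[i]
            y[i] = y[j]
            y[j] = tmp
        if _max_stat_value(y, min_width) >= t_obs:
            exceed += 1
            if exceed >= thresh:
                return (thresh + 1.0) / (n_perm + 1.0)
    return (exceed + 1.0) / (n_perm + 1.0)


def max_arc_stat(x: np.ndarray, min_width: int = 2) -> tuple[float, int, int]:
    """Best circular split (statistic, i, j) of one segment."""
    t, i, j = _max_stat(np.ascontiguousarray(x, dtype=np.float64), min_width)
    return float(t), int(i), int(j)


def perm_pvalue(
    x: np.ndarray, t_obs: float, n_perm: int, alpha: float, min_width: int, seed: int
) -> float:
    """Permutation p-value of the observed split statistic (seeded, early-abort)."""
    return float(
        _perm_pvalue(
            np.ascontiguousarray(x, dtype=np.float64),
            float(t_obs),
            int(n_perm),
            float(alpha),
            int(min_width),
            int(seed) & 0x7FFFFFFF,
        )
    )
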