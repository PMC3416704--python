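"""Numba kernels for occurrence-preserving shuffling of interaction records.

A network with N records is represented as a list of 2N *stubs* (endpoint
slots), protein i contributing exactly N_i stubs.  One randomized
realization is a perfect matching of the stubs with no self-pairs, drawn
uniformly from all such matchings.

Sampling scheme per realization:

1. Fisher-Yates shuffle of the stub list, pairing consecutive stubs
   (uniform over *all* matchings, self-pairs included).
2. Repair: while self-pairs remain, swap one endpoint of a self-pair with a
   random endpoint elsewhere, accepting only swaps that create no new
   self-pair.  Terminates with probability 1 whenever max N_i <= N.
3. Mixing: ``sweeps * N`` symmetric Metropolis double-swap moves (pick two
   pair slots, swap endpoints one of two ways, reject moves creating a
   self-pair).  The proposal is symmetric and the target uniform, so the
   chain's stationary distribution is uniform over self-pair-free matchings;
   the sweeps erase the small distributional bias of the bare repair step.

Realizations are independent draws (fresh shuffle each time); all
randomness flows from ``np.random.seed`` inside each kernel, making a run
bit-reproducible given (network, M, seed).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["ensemble_stats", "ensemble_hist", "single_matching"]


@njit(cache=True)
def _draw_matching(w, x, y, sweeps):  # pragma: no cover - exercised via wrappers
    n2 = w.shape[0]
    n = n2 // 2
    # Fisher-Yates
    for i in range(n2 - 1, 0, -1):
        j = np.random.randint(0, i + 1)
        t = w[i]
        w[i] = w[j]
        w[j] = t
    for i in range(n):
        x[i] = w[2 * i]
        y[i] = w[2 * i + 1]
    if n == 1:
        return
    # repair self-pairs
    stack = np.empty(n, dtype=np.int64)
    ns = 0
    for i in range(n):
        if x[i] == y[i]:
            stack[ns] = i
            ns += 1
    while ns > 0:
        i = stack[ns - 1]
        if x[i] != y[i]:
            ns -= 1
            continue
        q = np.random.randint(0, n)
        if q == i:
            continue
        if np.random.randint(0, 2) == 0:
            # swap y[i] <-> y[q]
            if x[i] != y[q] and x[q] != y[i]:
                t = y[i]
                y[i] = y[q]
                y[q] = t
                ns -= 1
        else:
            # swap y[i] <-> x[q]
            if x[i] != x[q] and y[q] != y[i]:
                t = y[i]
                y[i] = x[q]
                x[q] = t
                ns -= 1
    # mixing sweeps
    for _ in range(sweeps * n):
        p = np.random.randint(0, n)
        q = np.random.randint(0, n)
        if p == q:
            continue
        if np.random.randint(0, 2) == 0:
            if x[p] != y[q] and x[q] != y[p]:
                t = y[p]
                y[p] = y[q]
                y[q] = t
        else:
            if x[p] != x[q] and y[q] != y[p]:
                t = y[p]
                y[p] = x[q]
                x[q] = t


@njit(cache=True)
def _find_key(keys, key):  # pragma: no cover
    lo = 0
    hi = keys.shape[0]
    while lo < hi:
        mid = (lo + hi) // 2
        if keys[mid] < key:
            lo = mid + 1
        else:
            hi = mid
    if lo < keys.shape[0] and keys[lo] == key:
        return lo
    return -1


@njit(cache=True)
def ensemble_stats(stubs, keys, occ, n_prot, m, sweeps, seed):  # pragma: no cover
    """Stream M realizations; return (mean_R, M2, exceed_count) per observed
    pair, with mean/M2 maintained by Welford's one-pass update."""
    np.random.seed(seed)
    n = stubs.shape[0] // 2
    p_cnt = keys.shape[0]
    mean = np.zeros(p_cnt)
    m2 = np.zeros(p_cnt)
    exceed = np.zeros(p_cnt, dtype=np.int64)
    r = np.zeros(p_cnt, dtype=np.int64)
    w = stubs.copy()
    x = np.empty(n, dtype=np.int64)
    y = np.empty(n, dtype=np.int64)
    for it in range(m):
        _draw_matching(w, x, y, sweeps)
        for i in range(n):
            a = x[i]
            b = y[i]
            if a > b:
                a, b = b, a
            idx = _find_key(keys, a * n_prot + b)
            if idx >= 0:
                r[idx] += 1
        c = it + 1
        for k in range(p_cnt):
            rv = r[k]
            if rv >= occ[k]:
                exceed[k] += 1
            d = rv - mean[k]
            mean[k] += d / c
            m2[k] += d * (rv - mean[k])
            r[k] = 0
    return mean, m2, exceed


@njit(cache=True)
def ensemble_hist(stubs, keys, n_prot, m, sweeps, seed, max_r):  # pragma: no cover
    """Full per-pair occurrence histograms over M realizations."""
    np.random.seed(seed)
    n = stubs.shape[0] // 2
    p_cnt = keys.shape[0]
    hist = np.zeros((p_cnt, max_r + 1), dtype=np.int64)
    r = np.zeros(p_cnt, dtype=np.int64)
    w = stubs.copy()
    x = np.empty(n, dtype=np.int64)
    y = np.empty(n, dtype=np.int64)
    for _ in range(m):
        _draw_matching(w, x, y, sweeps)
        for i in range(n):
            a = x[i]
            b = y[i]
            if a > b:
                a, b = b, a
            idx = _find_key(keys, a * n_prot + b)
            if idx >= 0:
                r[idx] += 1
        for k in range(p_cnt):
            rv = r[k]
            if rv > max_r:
                rv = max_r
            hist[k, rv] += 1
            r[k] = 0
    return hist


@njit(cache=True)
def single_matching(stubs, sweeps, seed):  # pragma: no cover
    """One realization; returns the two endpoint arrays."""
    np.random.seed(seed)
    n = stubs.shape[0] // 2
    w = stubs.copy()
    x = np.empty(n, dtype=np.int64)
    y = np.empty(n, dtype=np.int64)
    _draw_matching(w, x, y, sweeps)
    return x, y
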