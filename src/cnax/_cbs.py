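"""Numba core for circular binary segmentation.

The arc statistic for splitting a probe vector x[0:n] at arc (i, j] is the
mean-difference t-like statistic between probes inside and outside the arc,
scaled by the overall sample SD.  With S the cumulative sum and
U[m] = S[m] - (m/n) * S[n] (the bridge), the statistic for an arc of width
k = j - i reduces to

    t(i, j) = |U[j] - U[i]| * sqrt(n / (k * (n - k))) / sd

Because the permutation null reshuffles the same multiset of values, sd is
permutation-invariant and the test can compare bridge maxima directly.  The
range bound max_i |U[i+k] - U[i]| <= max(U) - min(U) prunes whole arc widths
per permutation, so clearly significant splits cost O(n) per permutation.
Circular arcs need no extra scan: the statistic of an arc equals that of its
complement, and every circular split has a linear-arc representative.
"""

from __future__ import annotations

import math

import numba as nb
import numpy as np


@nb.njit(cache=True)
def _bridge(x):
    n = x.size
    tot = 0.0
    for i in range(n):
        tot += x[i]
    U = np.empty(n + 1)
    U[0] = 0.0
    c = 0.0
    for i in range(n):
        c += x[i]
        U[i + 1] = c - (i + 1) * tot / n
    return U


@nb.njit(cache=True)
def max_arc(x, min_width):
    """Best arc of ``x``: returns (T, i, j) maximizing |U[j]-U[i]| * w(j-i).

    T is in bridge units (not divided by the sample SD); i < j; arc widths k
    satisfy min_width <= k <= n - min_width.
    """
    n = x.size
    U = _bridge(x)
    best = -1.0
    bi = 0
    bj = n
    for k in range(min_width, n - min_width + 1):
        w = math.sqrt(n / (k * (n - k)))
        for i in range(0, n - k + 1):
            d = abs(U[i + k] - U[i]) * w
            if d > best:
                best = d
                bi = i
                bj = i + k
    return best, bi, bj


@nb.njit(cache=True)
def perm_pvalue(x, T, nperm, alpha, min_width, seed):
    """Permutation p-value for the observed max arc statistic T (bridge units).

    p = (1 + #{perm max >= T}) / (1 + nperm).  Stops early (returning a
    conservative p >= alpha) once significance at level alpha is impossible.
    """
    n = x.size
    y = x.copy()
    np.random.seed(seed)
    # exceedance budget: significance requires exceed + 1 < alpha * (nperm + 1)
    budget = alpha * (nperm + 1.0)
    exceed = 0
    wgrid = np.empty(n + 1)
    for k in range(min_width, n - min_width + 1):
        wgrid[k] = math.sqrt(n / (k * (n - k)))
    for p in range(nperm):
        for i in range(n - 1, 0, -1):
            j = np.random.randint(0, i + 1)
            tmp = y[i]
            y[i] = y[j]
            y[j] = tmp
        U = _bridge(y)
        umin = 0.0
        umax = 0.0
        for m in range(n + 1):
            if U[m] < umin:
                umin = U[m]
            if U[m] > umax:
                umax = U[m]
        rng_bound = umax - umin
        hit = False
        for k in range(min_width, n - min_width + 1):
            w = wgrid[k]
            if rng_bound * w < T:
                continue
            for i in range(0, n - k + 1):
                if abs(U[i + k] - U[i]) * w >= T:
                    hit = True
                    break
            if hit:
                break
        if hit:
            exceed += 1
            if exceed + 1 >= budget:
                return (exceed + 1.0) / (p + 2.0)
    return (exceed + 1.0) / (nperm + 1.0)
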