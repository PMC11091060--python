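"""Numba kernels for the O(N^2) feature estimators (approximate entropy and
nearest-neighbour divergence tracking for the largest Lyapunov exponent)."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def apen_phi_counts(x: np.ndarray, m: int, r: float):
    """Template match counts for ApEn at embedding dimensions m and m+1.

    Chebyshev distance, self-matches included.  Returns (counts_m, counts_m1)
    where counts_m[i] is the number of length-m templates within r of
    template i (N - m + 1 templates) and counts_m1 the analogue for m + 1.
    """
    n = x.size
    nm = n - m + 1   # number of m-templates
    nm1 = n - m      # number of (m+1)-templates
    counts_m = np.zeros(nm, dtype=np.int64)
    counts_m1 = np.zeros(nm1, dtype=np.int64)
    for i in range(nm):
        counts_m[i] += 1  # self match at m
        if i < nm1:
            counts_m1[i] += 1
        for j in range(i + 1, nm):
            d = 0.0
            for k in range(m):
                diff = abs(x[i + k] - x[j + k])
                if diff > d:
                    d = diff
            if d <= r:
                counts_m[i] += 1
                counts_m[j] += 1
                if i < nm1 and j < nm1:
                    diff = abs(x[i + m] - x[j + m])
                    if diff > d:
                        d = diff
                    if d <= r:
                        counts_m1[i] += 1
                        counts_m1[j] += 1
    return counts_m, counts_m1


@njit(cache=True)
def lyap_divergence(emb: np.ndarray, refs: np.ndarray, theiler: int,
                    max_steps: int):
    """Rosenstein divergence curve.

    For each reference index, find its nearest neighbour (Euclidean, outside
    the Theiler window) and accumulate log distances along the paired
    trajectories for ``max_steps`` steps.

    Returns (sum_logs, counts) per step; step 0 is the initial separation.
    """
    m, dim = emb.shape
    sum_logs = np.zeros(max_steps + 1)
    counts = np.zeros(max_steps + 1, dtype=np.int64)
    for idx in range(refs.size):
        i = refs[idx]
        best = 1e300
        best_j = -1
        for j in range(m):
            if abs(i - j) <= theiler:
                continue
            d = 0.0
            for k in range(dim):
                diff = emb[i, k] - emb[j, k]
                d += diff * diff
                if d >= best:
                    break
            if d < best:
                best = d
                best_j = j
        if best_j < 0:
            continue
        for step in range(max_steps + 1):
            ii = i + step
            jj = best_j + step
            if ii >= m or jj >= m:
                break
            d = 0.0
            for k in range(dim):
                diff = emb[ii, k] - emb[jj, k]
                d += diff * diff
            if d > 1e-300:
                sum_logs[step] += 0.5 * np.log(d)
                counts[step] += 1
    return sum_logs, counts
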