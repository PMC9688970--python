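"""Numba pair-scanning kernels behind the entropy estimators.

All kernels enumerate the unordered pairs of composite delay vectors and
accumulate per-vector statistics: the number of Chebyshev matches within a
hard tolerance (sample variant) and/or the summed fuzzy similarities
``exp(-d**s / r)`` (fuzzy variant).

Two loop shapes are used:

* :func:`match_counts` — element-at-a-time scan with an early exit as soon
  as the running maximum exceeds ``r``.  For tight tolerances almost every
  pair exits after one or two elements, which makes this the fastest shape
  for hard counting.
* :func:`fuzzy_sums` / :func:`pair_stats` — block-transposed scan.  The
  fuzzy similarity needs the completed maximum for (almost) every pair, so
  early exits buy nothing; instead the inner loop runs contiguously over a
  block of partner vectors in transposed layout ``(m, N)``, which the
  compiler can vectorize.

The fuzzy kernels skip the ``exp`` for pairs whose distance exceeds
``d_cut``, chosen by the caller so every skipped similarity lies below a
negligibility floor (see :data:`mventropy.entropy.TRUNC_EXPONENT`).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["match_counts", "fuzzy_sums", "pair_stats", "BLOCK"]

#: Partner-block width of the transposed kernels; sized so two blocks of
#: double-precision elements stay cache-resident.
BLOCK = 512


@njit(cache=True, fastmath=True)
def match_counts(vectors: np.ndarray, r: float) -> np.ndarray:
    """Per-vector count of Chebyshev matches ``d <= r``, self excluded.

    ``vectors`` has shape ``(N, m)``; returns an ``int64`` array of length N.
    """
    n, length = vectors.shape
    counts = np.zeros(n, dtype=np.int64)
    for a in range(n):
        for b in range(a + 1, n):
            matched = True
            for t in range(length):
                if abs(vectors[a, t] - vectors[b, t]) > r:
                    matched = False
                    break
            if matched:
                counts[a] += 1
                counts[b] += 1
    return counts


@njit(cache=True, fastmath=True)
def fuzzy_sums(vt: np.ndarray, r: float, s: float, d_cut: float) -> np.ndarray:
    """Per-vector sum of similarities ``exp(-d**s / r)``, self excluded.

    ``vt`` is the transposed vector matrix, shape ``(m, N)`` C-contiguous.
    Pairs with ``d > d_cut`` contribute zero.
    """
    length, n = vt.shape
    sums = np.zeros(n, dtype=np.float64)
    dmax = np.empty(BLOCK, dtype=np.float64)
    for a in range(n):
        for b0 in range(a + 1, n, BLOCK):
            b1 = min(b0 + BLOCK, n)
            w = b1 - b0
            for j in range(w):
                dmax[j] = 0.0
            for t in range(length):
                va = vt[t, a]
                row = vt[t]
                for j in range(w):
                    dmax[j] = max(dmax[j], abs(va - row[b0 + j]))
            acc = 0.0
            for j in range(w):
                if dmax[j] <= d_cut:
                    sim = math.exp(-(dmax[j] ** s) / r)
                    acc += sim
                    sums[b0 + j] += sim
            sums[a] += acc
    return sums


@njit(cache=True, fastmath=True)
def pair_stats(
    vt: np.ndarray, r_count: float, r_fuzzy: float, s: float, d_cut: float
):
    """Hard match counts at ``r_count`` and fuzzy sums at ``r_fuzzy``, one scan.

    Requires ``d_cut >= r_count`` so skipped pairs are guaranteed
    non-matches.  Returns ``(counts, sums)``.
    """
    length, n = vt.shape
    counts = np.zeros(n, dtype=np.int64)
    sums = np.zeros(n, dtype=np.float64)
    dmax = np.empty(BLOCK, dtype=np.float64)
    for a in range(n):
        for b0 in range(a + 1, n, BLOCK):
            b1 = min(b0 + BLOCK, n)
            w = b1 - b0
            for j in range(w):
                dmax[j] = 0.0
            for t in range(length):
                va = vt[t, a]
                row = vt[t]
                for j in range(w):
                    dmax[j] = max(dmax[j], abs(va - row[b0 + j]))
            acc = 0.0
            hits = 0
            for j in range(w):
                d = dmax[j]
                if d <= d_cut:
                    sim = math.exp(-(d**s) / r_fuzzy)
                    acc += sim
                    sums[b0 + j] += sim
                    if d <= r_count:
                        hits += 1
                        counts[b0 + j] += 1
            sums[a] += acc
            counts[a] += hits
    return counts, sums
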