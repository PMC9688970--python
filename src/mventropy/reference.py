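"""Deliberately naive reference implementations of the entropy estimators.

Everything here is written with explicit Python loops, straight from the
defining equations, and shares no code with the optimized estimators in
:mod:`mventropy.entropy`.  The module exists to validate the fast path: the
two implementations must agree to within 1e-10 on any input.  It is far too
slow for production use (quadratic pair loops in pure Python).

Also included are stand-alone bi-dimensional (grayscale, single-channel)
sample and fuzzy entropies, coded directly from the univariate-image
definitions, which the multivariate estimators must reproduce at ``q = 1``.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "msampen_naive",
    "mfuzen_naive",
    "sampen2d_naive",
    "fuzen2d_naive",
]


def _patch(x: np.ndarray, i: int, j: int, k: int, size: int) -> list[float]:
    """Row-major read-out of the ``size x size`` patch of channel k at (i, j)."""
    out = []
    for di in range(size):
        for dj in range(size):
            out.append(float(x[i + di, j + dj, k]))
    return out


def _composite(x: np.ndarray, i: int, j: int, sizes: list[int]) -> list[float]:
    vec: list[float] = []
    for k, size in enumerate(sizes):
        vec.extend(_patch(x, i, j, k, size))
    return vec


def _cheb(u: list[float], v: list[float]) -> float:
    return max(abs(a - b) for a, b in zip(u, v))


def _vector_sets(x: np.ndarray, M: list[int]):
    """Base vectors, plus one extended comparison group per channel.

    Extended vectors are compared only against vectors of the same extended
    embedding shape (corresponding patch positions must exist for the
    maximum-norm distance to be meaningful).
    """
    h, w, q = x.shape
    n = max(M)
    base = [
        _composite(x, i, j, list(M))
        for i in range(h - n)
        for j in range(w - n)
    ]
    groups = []
    for k in range(q):
        sizes = [m + 1 if kk == k else m for kk, m in enumerate(M)]
        groups.append(
            [
                _composite(x, i, j, sizes)
                for i in range(h - n)
                for j in range(w - n)
            ]
        )
    return base, groups


def _mean_count_freq(vectors, r: float, mode: str, denom: float, outer: float) -> float:
    """Mean frequency of Chebyshev matches within r, self excluded."""
    counts = []
    for a, va in enumerate(vectors):
        c = 0
        for b, vb in enumerate(vectors):
            if a != b and _cheb(va, vb) <= r:
                c += 1
        counts.append(c)
    if mode == "consistent":
        return sum(c / (len(vectors) - 1) for c in counts) / len(vectors)
    return sum(counts) / denom / outer


def _mean_sim_freq(vectors, r: float, s: float, mode: str, denom: float, outer: float) -> float:
    """Mean similarity exp(-d**s/r) over ordered pairs, self excluded."""
    sums = []
    for a, va in enumerate(vectors):
        total = 0.0
        for b, vb in enumerate(vectors):
            if a != b:
                total += math.exp(-(_cheb(va, vb) ** s) / r)
        sums.append(total)
    if mode == "consistent":
        return sum(t / (len(vectors) - 1) for t in sums) / len(vectors)
    return sum(sums) / denom / outer


def _multi_freqs(x, M, r, mode, sim_fn):
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        x = x[:, :, np.newaxis]
    h, w, q = x.shape
    M = [int(m) for m in M]
    n = max(M)
    n_m = (h - n) * (w - n)
    base, groups = _vector_sets(x, M)
    b_m = sim_fn(base, mode, n_m - n - 1, n_m - n)
    # weighted mean over all extended vectors == per-group stats combined
    if mode == "consistent":
        total_vectors = sum(len(g) for g in groups)
        b_m1 = (
            sum(sim_fn(g, mode, 0, 0) * len(g) for g in groups) / total_vectors
        )
    else:
        denom = q * (n_m - n) - 1
        outer = q * (n_m - n)
        b_m1 = sum(sim_fn(g, "literal-sum", denom, 1.0) for g in groups) / outer
    return b_m, b_m1


def msampen_naive(x, M, r: float, normalization: str = "consistent") -> float:
    """Literal multivariate sample entropy; NaN when a frequency vanishes."""

    def fn(vectors, mode, denom, outer):
        if mode == "literal-sum":
            return _mean_count_freq(vectors, r, "literal", denom, outer)
        return _mean_count_freq(vectors, r, mode, denom, outer)

    b_m, b_m1 = _multi_freqs(x, M, r, normalization, fn)
    if b_m == 0.0 or b_m1 == 0.0:
        return math.nan
    return -math.log(b_m1 / b_m)


def mfuzen_naive(x, M, r: float, s: float, normalization: str = "consistent") -> float:
    """Literal multivariate fuzzy entropy."""

    def fn(vectors, mode, denom, outer):
        if mode == "literal-sum":
            return _mean_sim_freq(vectors, r, s, "literal", denom, outer)
        return _mean_sim_freq(vectors, r, s, mode, denom, outer)

    b_m, b_m1 = _multi_freqs(x, M, r, normalization, fn)
    if b_m == 0.0 or b_m1 == 0.0:
        return math.nan
    return -math.log(b_m1 / b_m)


def _gray_patches(x: np.ndarray, m: int, n: int):
    h, w = x.shape
    out = []
    for i in range(h - n):
        for j in range(w - n):
            out.append([float(x[i + di, j + dj]) for di in range(m) for dj in range(m)])
    return out


def sampen2d_naive(x, m: int, r: float) -> float:
    """Bi-dimensional sample entropy of a single-channel image.

    Template patches of size ``m`` and ``m + 1`` share the anchor grid set
    by ``m``; matching uses the Chebyshev distance with hard threshold
    ``r`` and self-matches are excluded.  Returns NaN when undefined.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 3:
        x = x[:, :, 0]

    def mean_freq(patches):
        total = 0.0
        for a, pa in enumerate(patches):
            c = sum(
                1
                for b, pb in enumerate(patches)
                if a != b and _cheb(pa, pb) <= r
            )
            total += c / (len(patches) - 1)
        return total / len(patches)

    b = mean_freq(_gray_patches(x, m, m))
    a = mean_freq(_gray_patches(x, m + 1, m))
    if b == 0.0 or a == 0.0:
        return math.nan
    return -math.log(a / b)


def fuzen2d_naive(x, m: int, r: float, s: float) -> float:
    """Bi-dimensional fuzzy entropy of a single-channel image."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 3:
        x = x[:, :, 0]

    def mean_sim(patches):
        total = 0.0
        for a, pa in enumerate(patches):
            t = sum(
                math.exp(-(_cheb(pa, pb) ** s) / r)
                for b, pb in enumerate(patches)
                if a != b
            )
            total += t / (len(patches) - 1)
        return total / len(patches)

    phi_m = mean_sim(_gray_patches(x, m, m))
    phi_m1 = mean_sim(_gray_patches(x, m + 1, m))
    if phi_m == 0.0 or phi_m1 == 0.0:
        return math.nan
    return -math.log(phi_m1 / phi_m)
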