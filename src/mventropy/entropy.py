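"""Multivariate sample and fuzzy entropy for multichannel images.

The estimators quantify the spatial irregularity of an ``H x W x q`` image
by template matching in a multivariate embedding space.  For an embedding
vector ``M = [m_1, ..., m_q]`` with ``n = max(M)``:

1. At every anchor ``(i, j)`` on the grid ``i = 0..H-n-1``, ``j = 0..W-n-1``
   (``N_m = (H-n)(W-n)`` anchors) a *composite delay vector* is formed by
   concatenating, channel by channel, the ``m_k x m_k`` pixel patch of
   channel ``k`` anchored at ``(i, j)``, each patch read row-major.  The
   composite dimension is ``m = sum(m_k**2)``.
2. Two vectors are compared with the Chebyshev (maximum-norm) distance over
   all their elements, channels pooled.
3. ``B^m(r)`` is the mean frequency with which a vector finds another vector
   within tolerance ``r``, self-matches excluded.
4. The embedding is then extended: from ``[m_1, ..., m_k, ..., m_q]`` the
   system may evolve to any ``[m_1, ..., m_k + 1, ..., m_q]``, giving
   ``q * N_m`` extended vectors (the anchor grid built from ``n`` leaves
   exactly the spare row and column the enlarged patch needs, so every
   anchor admits every extension).  ``B^{m+1}(r)`` is the mean match
   frequency over all extended vectors, each compared against the vectors
   sharing its extended embedding shape (the distance pairs corresponding
   patch positions, which only exist between identically-structured
   composites).
5. The multivariate sample entropy is ``-ln(B^{m+1}/B^m)``; it is undefined
   when either frequency is zero.

The fuzzy variant replaces the hard Heaviside match by the graded
similarity ``exp(-d**s / r)`` averaged over all pairs, which keeps the
estimate defined even when no pair falls within ``r``.

With ``q = 1`` both estimators reduce to the bi-dimensional (grayscale)
sample and fuzzy entropies.

Tolerance ``r`` is absolute, in the intensity units of the input: images
are expected to be z-normalized beforehand (see
:func:`mventropy.preprocessing.normalize`), which makes ``r`` a fraction of
the image's standard deviation.  The kernel itself neither checks nor
enforces normalization, so raw synthetic images can be analyzed directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._kernels import fuzzy_sums, match_counts, pair_stats
from .errors import ImageSizeError, ParameterError, ShapeError
from .image import MultichannelImage, as_pixels

__all__ = [
    "EmbeddingConfig",
    "EntropyResult",
    "build_composite_delay_vectors",
    "chebyshev_distance",
    "msampen_rgb",
    "mfuzen_rgb",
    "msampen_mfuzen_rgb",
]

#: Fuzzy similarities below ``exp(-TRUNC_EXPONENT)`` (about 1e-24) are
#: dropped by the optimized kernel.  The truncation is entirely inactive
#: whenever the data diameter is at most ``(TRUNC_EXPONENT * r)**(1/s)``
#: (e.g. intensities in [0, 1] with r >= 0.02, s = 2); otherwise the induced
#: absolute error is bounded by ``n_pairs * exp(-TRUNC_EXPONENT)``, orders
#: of magnitude below the leading terms of any similarity sum the estimate
#: can resolve.
TRUNC_EXPONENT = 55.0

_MODES = ("consistent", "literal")


@dataclass(frozen=True)
class EmbeddingConfig:
    """Embedding parameters for the multivariate entropy estimators.

    Attributes
    ----------
    M
        Per-channel patch sizes ``[m_1, ..., m_q]``, each ``>= 1``.  Length
        must equal the image channel count.
    r
        Matching tolerance (sample) or similarity scale (fuzzy), ``> 0``,
        in absolute intensity units.
    s
        Fuzzy power shaping the similarity fall-off, ``> 0``; required by
        the fuzzy estimator only.
    """

    M: tuple[int, ...]
    r: float
    s: float | None = None

    def __post_init__(self) -> None:
        raw = (self.M,) if np.isscalar(self.M) else tuple(self.M)
        M = tuple(int(m) for m in raw)
        object.__setattr__(self, "M", M)
        if len(M) < 1 or any(m < 1 for m in M):
            raise ParameterError(f"embedding sizes must all be >= 1, got M={M}")
        if not (float(self.r) > 0.0):
            raise ParameterError(f"tolerance r={self.r} must be > 0")
        if self.s is not None and not (float(self.s) > 0.0):
            raise ParameterError(f"fuzzy power s={self.s} must be > 0")

    @property
    def n(self) -> int:
        """Largest per-channel embedding size; sets the shared anchor grid."""
        return max(self.M)

    @property
    def q(self) -> int:
        return len(self.M)

    def validate_for(self, shape: tuple[int, int, int], require_pairs: bool = True) -> None:
        """Check the config against an image shape ``(H, W, q)``.

        With ``require_pairs`` (the default for entropy estimation) the
        anchor grid must hold at least two delay vectors per axis; bare
        vector construction only needs one.
        """
        h, w, q = shape
        if q != self.q:
            raise ParameterError(
                f"embedding vector has {self.q} entries for a {q}-channel image"
            )
        n = self.n
        least = 2 if require_pairs else 1
        if h - n < least or w - n < least:
            raise ImageSizeError(
                f"image {h}x{w} too small for n={n}: need H-n >= {least} and "
                f"W-n >= {least}"
            )


@dataclass(frozen=True)
class EntropyResult:
    """Entropy estimate plus the intermediate match statistics.

    ``b_m`` and ``b_m1`` hold the mean frequency of occurrence (or mean
    similarity, fuzzy variant) at the base and extended dimensions.  When
    either vanishes the sample estimate is undefined: ``defined`` is False
    and ``value`` is NaN — never an exception, so multiscale profiles can
    record gaps.
    """

    value: float
    b_m: float
    b_m1: float
    n_vectors: int
    defined: bool
    method: str = ""

    @staticmethod
    def from_frequencies(b_m: float, b_m1: float, n_vectors: int, method: str) -> "EntropyResult":
        defined = b_m > 0.0 and b_m1 > 0.0
        value = -math.log(b_m1 / b_m) if defined else math.nan
        return EntropyResult(value, b_m, b_m1, n_vectors, defined, method)


def chebyshev_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Maximum absolute elementwise difference between two composite vectors."""
    u = np.asarray(u, dtype=np.float64).ravel()
    v = np.asarray(v, dtype=np.float64).ravel()
    if u.shape != v.shape:
        raise ShapeError(f"vector lengths differ: {u.shape[0]} vs {v.shape[0]}")
    return float(np.max(np.abs(u - v))) if u.size else 0.0


def _patch_columns(x: np.ndarray, M: tuple[int, ...], sizes: tuple[int, ...]) -> np.ndarray:
    """Stack per-channel patches of the given sizes over the common anchor grid.

    ``sizes[k]`` is the patch edge for channel ``k``; the anchor grid is the
    base grid set by ``n = max(M)``.  Returns ``(N_m, sum(sizes**2))`` with
    anchors enumerated row-major and each patch read row-major.
    """
    h, w, _ = x.shape
    n = max(M)
    nr, nc = h - n, w - n
    cols = []
    for k, size in enumerate(sizes):
        for di in range(size):
            for dj in range(size):
                cols.append(x[di : di + nr, dj : dj + nc, k])
    stacked = np.stack(cols, axis=-1)  # (nr, nc, m)
    return np.ascontiguousarray(stacked.reshape(nr * nc, -1))


def build_composite_delay_vectors(
    img: MultichannelImage | np.ndarray, cfg: EmbeddingConfig
) -> np.ndarray:
    """Return the ``N_m x m`` matrix of composite delay vectors.

    Row order follows the anchor grid row-major: anchor ``(i, j)`` maps to
    row ``i * (W - n) + j``.
    """
    x = as_pixels(img)
    cfg.validate_for(x.shape, require_pairs=False)
    return _patch_columns(x, cfg.M, cfg.M)


def _extended_groups(x: np.ndarray, M: tuple[int, ...]) -> list[np.ndarray]:
    """Extended-dimension vector matrices, one comparison group per channel.

    Extending channel ``k`` enlarges its patch from ``m_k`` to ``m_k + 1``,
    giving ``N_m`` extended vectors per channel (``q * N_m`` in total).
    Comparisons are restricted to vectors sharing the same extended
    embedding shape: the maximum-norm distance is defined over pixels in
    corresponding patch positions, which only exist between
    identically-structured composites.  Pooling across extension channels
    would compare structurally misaligned elements and make the estimate
    depend on the (arbitrary) patch read-out order, destroying its
    invariance under transposition, rotation and channel permutation.
    """
    return [
        _patch_columns(
            x, M, tuple(m + 1 if idx == k else m for idx, m in enumerate(M))
        )
        for k in range(len(M))
    ]


def _frequencies(
    per_vector: list[np.ndarray],
    group_sizes: list[int],
    mode: str,
    literal_denom: float,
    literal_outer: float,
) -> float:
    """Average per-vector counts/sums into a mean frequency of occurrence."""
    if mode == "consistent":
        parts = [vec / (size - 1) for vec, size in zip(per_vector, group_sizes)]
        return float(np.concatenate(parts).mean())
    total = float(sum(vec.sum() for vec in per_vector))
    return total / literal_denom / literal_outer


def _transposed(matrix: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(matrix.T)


def _entropy(
    img: MultichannelImage | np.ndarray,
    cfg: EmbeddingConfig,
    normalization: str,
    want: str,
    r_sample: float | None = None,
):
    """Shared driver: scan base and extended vectors, average frequencies.

    ``want`` selects the statistic(s): ``"sample"``, ``"fuzzy"`` or
    ``"both"`` (one combined scan, counts taken at ``r_sample``).
    """
    if normalization not in _MODES:
        raise ParameterError(
            f"normalization must be one of {_MODES}, got {normalization!r}"
        )
    x = as_pixels(img)
    cfg.validate_for(x.shape)
    n, q, r = cfg.n, cfg.q, float(cfg.r)
    n_m = (x.shape[0] - n) * (x.shape[1] - n)
    if normalization == "literal" and n_m - n - 1 < 1:
        raise ImageSizeError(
            f"literal normalization needs N_m - n - 1 >= 1, got N_m={n_m}, n={n}"
        )

    if want != "sample":
        if cfg.s is None:
            raise ParameterError("fuzzy entropy requires the fuzzy power s")
        s = float(cfg.s)
        d_cut = (TRUNC_EXPONENT * r) ** (1.0 / s)

    if want == "sample":

        def stats(matrix: np.ndarray) -> tuple[np.ndarray, ...]:
            return (match_counts(matrix, r).astype(np.float64),)

    elif want == "fuzzy":

        def stats(matrix: np.ndarray) -> tuple[np.ndarray, ...]:
            return (fuzzy_sums(_transposed(matrix), r, s, d_cut),)

    else:  # both, one scan
        rc = r if r_sample is None else float(r_sample)
        cut = max(rc, d_cut)

        def stats(matrix: np.ndarray) -> tuple[np.ndarray, ...]:
            counts, sums = pair_stats(_transposed(matrix), rc, r, s, cut)
            return counts.astype(np.float64), sums

    base_stats = stats(build_composite_delay_vectors(x, cfg))
    groups = _extended_groups(x, cfg.M)
    group_stats = [stats(g) for g in groups]
    group_sizes = [g.shape[0] for g in groups]

    results = []
    for channel, method in enumerate(
        ("msampen", "mfuzen") if want == "both" else (want,)
    ):
        b_m = _frequencies(
            [base_stats[channel]], [n_m], normalization, n_m - n - 1, n_m - n
        )
        b_m1 = _frequencies(
            [gs[channel] for gs in group_stats],
            group_sizes,
            normalization,
            q * (n_m - n) - 1,
            q * (n_m - n),
        )
        name = {"sample": "msampen", "fuzzy": "mfuzen"}.get(method, method)
        results.append(EntropyResult.from_frequencies(b_m, b_m1, n_m, name))
    return tuple(results) if want == "both" else results[0]


def msampen_rgb(
    img: MultichannelImage | np.ndarray,
    cfg: EmbeddingConfig,
    normalization: str = "consistent",
) -> EntropyResult:
    """Multivariate sample entropy of a multichannel image.

    Parameters
    ----------
    img
        Image of shape ``(H, W, q)``; z-normalized input is recommended so
        ``cfg.r`` reads as a fraction of the standard deviation.
    cfg
        Embedding sizes and tolerance; ``cfg.s`` is ignored.
    normalization
        ``"consistent"`` (default) divides each per-vector match count by
        the number of comparison vectors (``N_m - 1`` at the base dimension,
        group size minus one at the extended dimension), keeping every
        frequency in ``[0, 1]``.  ``"literal"`` applies the printed
        constants ``1/(N_m - n - 1)`` and ``1/(q (N_m - n) - 1)`` verbatim;
        the two modes differ by a constant offset in the entropy value.

    Returns
    -------
    EntropyResult
        With ``defined=False`` and a NaN value when no matches occur at
        either dimension (the hard-threshold estimator's known failure mode
        on highly irregular data).
    """
    return _entropy(img, cfg, normalization, want="sample")


def mfuzen_rgb(
    img: MultichannelImage | np.ndarray,
    cfg: EmbeddingConfig,
    normalization: str = "consistent",
) -> EntropyResult:
    """Multivariate fuzzy entropy of a multichannel image.

    Hard match counting is replaced by the similarity ``exp(-d**s / r)``
    averaged over all ordered pairs (self-matches excluded at both
    dimensions), so the estimate stays defined where the sample variant
    breaks down.  See :func:`msampen_rgb` for the shared conventions.
    """
    return _entropy(img, cfg, normalization, want="fuzzy")


def msampen_mfuzen_rgb(
    img: MultichannelImage | np.ndarray,
    cfg: EmbeddingConfig,
    r_sample: float | None = None,
    normalization: str = "consistent",
) -> tuple[EntropyResult, EntropyResult]:
    """Both entropies of one image from a single pair scan.

    The dominant cost of either estimator is the enumeration of vector
    pairs; this helper amortizes it by accumulating the hard match counts
    and the fuzzy similarities together.  ``cfg.r`` is the fuzzy similarity
    scale (``cfg.s`` required); ``r_sample``, defaulting to ``cfg.r``, is
    the hard tolerance for the sample measure — the hard threshold typically
    needs a larger value than the fuzzy scale to keep the estimate defined
    on irregular data.

    Returns ``(sample_result, fuzzy_result)``.
    """
    return _entropy(img, cfg, normalization, want="both", r_sample=r_sample)
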