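"""Coarse-graining and multiscale entropy profiles.

Multiscale entropy evaluates an estimator on progressively coarse-grained
copies of the image.  At scale factor ``tau`` each channel is partitioned
into non-overlapping ``tau x tau`` blocks starting at the top-left corner;
every block is replaced by its mean and trailing rows/columns that do not
fill a block are discarded.  This is the two-dimensional analogue of the
standard 1-D coarse-graining.  No re-normalization is applied after
coarse-graining and the tolerance ``r`` stays fixed across scales, so the
variance reduction of uncorrelated data shows up as the classic signature:
entropy of white noise falls with ``tau`` while correlated textures hold
their entropy across scales.

The ordered vector of entropies for ``tau = 1..tau_max`` — the
:class:`MultiscaleProfile` — is the feature vector consumed by the
classification harness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .entropy import EmbeddingConfig, EntropyResult, mfuzen_rgb, msampen_rgb
from .errors import ImageSizeError, ParameterError
from .image import MultichannelImage, as_pixels

__all__ = ["MultiscaleProfile", "coarse_grain", "multiscale_profile"]

_METHODS = {"msampen": msampen_rgb, "mfuzen": mfuzen_rgb}


@dataclass(frozen=True)
class MultiscaleProfile:
    """Entropy values over scales ``tau = 1..tau_max``.

    ``values[t]`` is NaN where the estimator was undefined or the
    coarse-grained image fell below the embedding's size requirement; the
    ``defined`` mask and per-scale ``reasons`` record why.
    """

    method: str
    cfg: EmbeddingConfig
    taus: tuple[int, ...]
    values: np.ndarray
    defined: np.ndarray
    reasons: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.taus)

    @property
    def tau_max(self) -> int:
        return self.taus[-1]


def coarse_grain(img: MultichannelImage | np.ndarray, tau: int) -> MultichannelImage:
    """Block-mean coarse-graining at scale factor ``tau``.

    The output has shape ``(floor(H/tau), floor(W/tau), q)``; the global
    mean over the retained region is conserved exactly.
    """
    tau = int(tau)
    if tau < 1:
        raise ParameterError(f"scale factor tau={tau} must be >= 1")
    px = as_pixels(img)
    h, w, q = px.shape
    ht, wt = h // tau, w // tau
    if ht < 1 or wt < 1:
        raise ImageSizeError(f"tau={tau} larger than image {h}x{w}")
    if tau == 1:
        out = px
    else:
        out = (
            px[: ht * tau, : wt * tau]
            .reshape(ht, tau, wt, tau, q)
            .mean(axis=(1, 3))
        )
    if isinstance(img, MultichannelImage):
        return img.with_pixels(out, f"cg(tau={tau})")
    return MultichannelImage(out, provenance=f"cg(tau={tau})")


def multiscale_profile(
    img: MultichannelImage | np.ndarray,
    cfg: EmbeddingConfig,
    method: str = "msampen",
    tau_max: int = 10,
    normalization: str = "consistent",
) -> MultiscaleProfile:
    """Entropy of the image at every scale ``tau = 1..tau_max``.

    Scales where the coarse-grained image is too small for the embedding, or
    where the sample estimator finds no matches, are recorded as undefined
    (NaN + reason) rather than raised, so profiles over an image set stay
    aligned.
    """
    if method not in _METHODS:
        raise ParameterError(f"method must be one of {tuple(_METHODS)}, got {method!r}")
    tau_max = int(tau_max)
    if tau_max < 1:
        raise ParameterError(f"tau_max={tau_max} must be >= 1")
    estimator = _METHODS[method]
    values = np.full(tau_max, np.nan)
    defined = np.zeros(tau_max, dtype=bool)
    reasons: list[str] = []
    for t in range(1, tau_max + 1):
        try:
            result: EntropyResult = estimator(
                coarse_grain(img, t), cfg, normalization=normalization
            )
        except ImageSizeError as exc:
            reasons.append(f"size: {exc}")
            continue
        values[t - 1] = result.value
        defined[t - 1] = result.defined
        reasons.append("" if result.defined else "no matches at tolerance r")
    return MultiscaleProfile(
        method=method,
        cfg=cfg,
        taus=tuple(range(1, tau_max + 1)),
        values=values,
        defined=defined,
        reasons=tuple(reasons),
    )
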