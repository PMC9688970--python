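"""Image pre-processing: center crop, z-normalization, grayscale conversion.

The entropy pipeline prepares every image the same way: crop a centered
window (to bound the quadratic cost of template matching), then z-normalize
the intensities so the tolerance ``r`` is expressed in units of the image's
own standard deviation.  Normalization is pooled over all pixels and
channels by default — a single mean and standard deviation per image — so
that the relative intensity relationships *between* channels, which the
multivariate distance compares, are preserved.  ``per_channel=True`` is
available for workflows that want each channel standardized separately.

The standard deviation uses the population convention (divide by the pixel
count, ``ddof=0``).
"""

from __future__ import annotations

import numpy as np

from .errors import ChannelError, DegenerateImageError, ImageSizeError
from .image import MultichannelImage, as_pixels

__all__ = ["center_crop", "normalize", "to_grayscale", "LUMA_WEIGHTS"]

#: ITU-R BT.601 luma weights for R, G, B.
LUMA_WEIGHTS = np.array([0.2989, 0.5870, 0.1140])


def _wrap(img, pixels: np.ndarray, note: str) -> MultichannelImage:
    if isinstance(img, MultichannelImage):
        return img.with_pixels(pixels, note)
    return MultichannelImage(pixels, provenance=note)


def center_crop(
    img: MultichannelImage | np.ndarray, size: int | tuple[int, int]
) -> MultichannelImage:
    """Crop a centered ``size`` window from the image.

    ``size`` is either a single integer (square crop) or ``(height, width)``.
    The window offset on each axis is ``floor((source - target) / 2)``, so
    for odd leftovers the extra row/column stays on the bottom/right.
    """
    px = as_pixels(img)
    th, tw = (size, size) if np.isscalar(size) else (int(size[0]), int(size[1]))
    h, w = px.shape[:2]
    if th < 1 or tw < 1:
        raise ImageSizeError(f"non-positive crop size {(th, tw)}")
    if th > h or tw > w:
        raise ImageSizeError(f"crop {(th, tw)} larger than image {(h, w)}")
    r0 = (h - th) // 2
    c0 = (w - tw) // 2
    return _wrap(img, px[r0 : r0 + th, c0 : c0 + tw], f"crop{th}x{tw}")


def normalize(
    img: MultichannelImage | np.ndarray, per_channel: bool = False
) -> MultichannelImage:
    """Z-normalize intensities to mean 0 and standard deviation 1.

    Pooled over all pixels and channels by default; ``per_channel=True``
    standardizes each channel on its own statistics.  A constant image (zero
    spread) raises :class:`DegenerateImageError`.
    """
    px = as_pixels(img)
    if per_channel:
        mu = px.mean(axis=(0, 1), keepdims=True)
        sd = px.std(axis=(0, 1), keepdims=True)
        if np.any(sd == 0.0):
            raise DegenerateImageError("constant channel: zero standard deviation")
    else:
        mu = px.mean()
        sd = px.std()
        if sd == 0.0:
            raise DegenerateImageError("constant image: zero standard deviation")
    return _wrap(img, (px - mu) / sd, "znorm" + ("/ch" if per_channel else ""))


def to_grayscale(img: MultichannelImage | np.ndarray) -> MultichannelImage:
    """Collapse an RGB image to one luma channel (ITU-R BT.601 weights).

    Only defined for ``q = 3``; the univariate entropy baselines run on the
    result.
    """
    px = as_pixels(img)
    if px.shape[2] != 3:
        raise ChannelError(f"grayscale conversion needs q=3, got q={px.shape[2]}")
    gray = px @ LUMA_WEIGHTS
    return _wrap(img, gray[:, :, np.newaxis], "gray601")
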