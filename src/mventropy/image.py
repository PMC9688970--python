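"""The multichannel image container and file I/O.

A :class:`MultichannelImage` is an ``H x W x q`` array of real-valued pixel
intensities plus light metadata.  It is the universal carrier throughout the
package: raw images read from disk, synthetic MIX images, normalized images
and coarse-grained images are all instances of it.

Raster files (PNG/TIFF/JPEG) are read through :mod:`imageio` and scaled to
floats in ``[0, 1]``.  Synthetic float-valued images travel through ``.npy``
files, NumPy's portable array container, so that no precision is lost between
generation and entropy computation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import ChannelError, ImageSizeError

__all__ = [
    "MultichannelImage",
    "as_pixels",
    "read_image",
    "load_array",
    "save_array",
    "render_png",
]

RGB_NAMES = ("R", "G", "B")


@dataclass(frozen=True)
class MultichannelImage:
    """An ``H x W x q`` block of real-valued pixel intensities.

    Parameters
    ----------
    pixels
        Array of shape ``(H, W, q)``; a 2-D array is promoted to a single
        channel.  Values must be finite.
    channel_names
        Optional per-channel labels, e.g. ``("R", "G", "B")``.
    provenance
        Free-text origin tag (source path or generator description).
    """

    pixels: np.ndarray
    channel_names: tuple[str, ...] | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim == 2:
            px = px[:, :, np.newaxis]
        if px.ndim != 3:
            raise ImageSizeError(f"expected a 2-D or 3-D array, got ndim={px.ndim}")
        if px.shape[0] < 1 or px.shape[1] < 1 or px.shape[2] < 1:
            raise ImageSizeError(f"empty image of shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ImageSizeError("image contains non-finite values")
        object.__setattr__(self, "pixels", px)
        if self.channel_names is not None:
            names = tuple(self.channel_names)
            if len(names) != px.shape[2]:
                raise ChannelError(
                    f"{len(names)} channel names for {px.shape[2]} channels"
                )
            object.__setattr__(self, "channel_names", names)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, note: str = "") -> "MultichannelImage":
        """Return a copy carrying new pixel data and an appended provenance note."""
        prov = f"{self.provenance}|{note}" if note else self.provenance
        names = self.channel_names
        px = np.asarray(pixels)
        if px.ndim == 2:
            px = px[:, :, np.newaxis]
        if names is not None and px.shape[-1] != len(names):
            names = None
        return replace(self, pixels=px, channel_names=names, provenance=prov)


def as_pixels(img: "MultichannelImage | np.ndarray") -> np.ndarray:
    """Coerce an image argument to a float64 ``(H, W, q)`` array.

    Accepts either a :class:`MultichannelImage` or a bare 2-D/3-D array, so
    the numerical routines can be called directly on NumPy data.
    """
    if isinstance(img, MultichannelImage):
        return img.pixels
    px = np.asarray(img, dtype=np.float64)
    if px.ndim == 2:
        px = px[:, :, np.newaxis]
    if px.ndim != 3:
        raise ImageSizeError(f"expected a 2-D or 3-D array, got ndim={px.ndim}")
    return px


def read_image(path: str | Path) -> MultichannelImage:
    """Read a raster image file into float intensities in ``[0, 1]``.

    Integer sample formats are divided by their dtype maximum (255 for 8-bit,
    65535 for 16-bit); float files are taken as-is.  An alpha channel, if
    present, is dropped.
    """
    import imageio.v3 as iio

    raw = iio.imread(Path(path))
    arr = np.asarray(raw)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
        arr = arr.astype(np.float64) / scale
    else:
        arr = arr.astype(np.float64)
    names = RGB_NAMES if arr.ndim == 3 and arr.shape[2] == 3 else None
    return MultichannelImage(arr, channel_names=names, provenance=str(path))


def save_array(img: "MultichannelImage | np.ndarray", path: str | Path) -> Path:
    """Write float pixel data to a ``.npy`` container (lossless)."""
    path = Path(path)
    np.save(path, as_pixels(img))
    return path if path.suffix == ".npy" else path.with_suffix(path.suffix + ".npy")


def load_array(path: str | Path) -> MultichannelImage:
    """Read pixel data previously written by :func:`save_array`."""
    return MultichannelImage(np.load(Path(path)), provenance=str(path))


def render_png(
    img: "MultichannelImage | np.ndarray", path: str | Path
) -> Path:
    """Render float pixels to an 8-bit PNG, min-max scaled.

    For visual inspection only: the scaling is lossy and entropy must always
    be computed on the float data.
    """
    import imageio.v3 as iio

    px = as_pixels(img)
    lo, hi = float(px.min()), float(px.max())
    scaled = np.zeros_like(px) if hi == lo else (px - lo) / (hi - lo)
    u8 = np.round(scaled * 255).astype(np.uint8)
    if u8.shape[2] == 1:
        u8 = u8[:, :, 0]
    path = Path(path)
    iio.imwrite(path, u8)
    return path
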