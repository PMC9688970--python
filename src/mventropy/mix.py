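"""MIX processes: synthetic signals and images of controlled irregularity.

A MIX(p) process mixes a deterministic sinusoidal template with uniform white
noise: each sample (or pixel) is replaced by a draw from Uniform[-3, 3] with
probability ``p`` and keeps the template value otherwise.  The parameter
``p`` is therefore a ground-truth irregularity dial — ``p = 0`` yields a
perfectly periodic pattern, ``p = 1`` pure noise — which makes the family
the standard benchmark for entropy estimators.

Two generators are provided:

* :func:`generate_mix1d` — a multivariate 1-D signal of ``q`` variates whose
  template is ``sin(2*pi*i/12)``;
* :func:`generate_mix2d` — a multichannel image whose template is the doubly
  periodic surface ``sin(2*pi*i/12) + sin(2*pi*j/12)``.

By default each channel is an independent MIX process (independent Bernoulli
mask ``Z`` and noise ``Y`` per channel).  ``shared_mask=True`` shares the
mask ``Z`` across channels, i.e. the same pixels are noise-corrupted in every
channel, while the noise values stay channel-independent.

Reproducibility contract: one seeded generator per call; the mask ``Z`` is
drawn first, then the noise ``Y``, each in a single C-order (channel-minor)
block, so identical parameters give bit-identical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .image import MultichannelImage, RGB_NAMES

__all__ = ["MixParams", "generate_mix1d", "generate_mix2d", "NOISE_LOW", "NOISE_HIGH"]

NOISE_LOW = -3.0
NOISE_HIGH = 3.0
SINE_PERIOD = 12.0


@dataclass(frozen=True)
class MixParams:
    """Parameters of one MIX realization.

    Attributes
    ----------
    p
        Probability that a sample/pixel is noise; must lie in ``[0, 1]``.
    shape
        ``N`` (1-D) or ``(H, W)`` (2-D), positive integers.
    q
        Number of variates / channels, ``>= 1`` (3 for RGB).
    seed
        Seed of the ``numpy`` Generator used for this realization.
    shared_mask
        Share the Bernoulli mask ``Z`` across channels (literal reading of
        the un-subscripted mask); default draws it per channel.
    """

    p: float
    shape: int | tuple[int, int]
    q: int = 3
    seed: int = 0
    shared_mask: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= float(self.p) <= 1.0):
            raise ParameterError(f"noise probability p={self.p} outside [0, 1]")
        if int(self.q) < 1:
            raise ParameterError(f"channel count q={self.q} must be >= 1")
        dims = (self.shape,) if np.isscalar(self.shape) else tuple(self.shape)
        if any(int(d) < 1 for d in dims):
            raise ParameterError(f"non-positive dimensions in shape {self.shape}")

    @property
    def dims(self) -> tuple[int, ...]:
        return (int(self.shape),) if np.isscalar(self.shape) else tuple(
            int(d) for d in self.shape
        )


def _mix(template: np.ndarray, params: MixParams) -> np.ndarray:
    """Mix a template of shape ``dims`` with uniform noise, channel-wise."""
    dims = template.shape
    q = int(params.q)
    rng = np.random.default_rng(params.seed)
    mask_shape = dims if params.shared_mask else dims + (q,)
    z = rng.random(mask_shape) < params.p
    if params.shared_mask:
        z = np.broadcast_to(z[..., np.newaxis], dims + (q,))
    y = rng.uniform(NOISE_LOW, NOISE_HIGH, size=dims + (q,))
    out = np.where(z, y, template[..., np.newaxis])
    return np.ascontiguousarray(out, dtype=np.float64)


def generate_mix1d(params: MixParams) -> np.ndarray:
    """Generate a MIX(p) multivariate signal of shape ``(N, q)``.

    Sample ``i`` of every channel equals ``sin(2*pi*i/12)`` where the mask is
    0 and a Uniform[-3, 3] draw where it is 1 (0-based ``i``).
    """
    dims = params.dims
    if len(dims) != 1:
        raise ParameterError(f"1-D generation needs a scalar length, got {params.shape}")
    (n,) = dims
    i = np.arange(n, dtype=np.float64)
    template = np.sin(2.0 * np.pi * i / SINE_PERIOD)
    return _mix(template, params)


def generate_mix2d(params: MixParams) -> MultichannelImage:
    """Generate a MIX(p) multichannel image of shape ``(H, W, q)``.

    The template is ``sin(2*pi*i/12) + sin(2*pi*j/12)`` with 0-based row
    index ``i`` and column index ``j`` — a doubly periodic surface of period
    12 along both axes.
    """
    dims = params.dims
    if len(dims) != 2:
        raise ParameterError(f"2-D generation needs shape (H, W), got {params.shape}")
    h, w = dims
    i = np.arange(h, dtype=np.float64)[:, np.newaxis]
    j = np.arange(w, dtype=np.float64)[np.newaxis, :]
    template = np.sin(2.0 * np.pi * i / SINE_PERIOD) + np.sin(2.0 * np.pi * j / SINE_PERIOD)
    pixels = _mix(template, params)
    names = RGB_NAMES if params.q == 3 else None
    tag = (
        f"mix2d(p={params.p},shape={h}x{w},q={params.q},seed={params.seed}"
        f"{',shared_mask' if params.shared_mask else ''})"
    )
    return MultichannelImage(pixels, channel_names=names, provenance=tag)
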