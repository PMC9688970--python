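"""Exception hierarchy.

All errors raised on bad user input derive from :class:`MventropyError`
(itself a ``ValueError``) so callers can catch one type.
"""


class MventropyError(ValueError):
    """Base class for all parameter / input errors raised by this package."""


class ParameterError(MventropyError):
    """A scalar parameter is outside its admissible range."""


class ImageSizeError(MventropyError):
    """An image is too small for the requested operation (crop, embedding, scale)."""


class DegenerateImageError(MventropyError):
    """The image carries no usable intensity spread (e.g. constant image)."""


class ChannelError(MventropyError):
    """Channel count is incompatible with the requested operation."""


class ShapeError(MventropyError):
    """Array shapes are incompatible (e.g. vectors of different length)."""


class ConfigError(MventropyError):
    """A run configuration is inconsistent; the message names the field."""
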