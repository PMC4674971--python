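"""Exception hierarchy for kinesmooth.

All library errors derive from :class:`KinesmoothError` so callers can catch
one type at the CLI boundary.
"""


class KinesmoothError(Exception):
    """Base class for all kinesmooth errors."""


class InputTooShortError(KinesmoothError):
    """Signal has too few samples for the requested operation."""


class ShapeError(KinesmoothError):
    """Channel count or array shape does not match the operation's contract."""


class ParameterError(KinesmoothError):
    """A parameter is outside its valid range."""


class DegenerateInputError(KinesmoothError):
    """Input carries no movement (e.g. an all-zero speed profile).

    Smoothness of a fixed posture is undefined, so measures reject such
    profiles instead of returning a number.
    """


class SegmentationError(KinesmoothError):
    """Segmentation boundaries are invalid (non-increasing, empty...)."""


class RangeError(KinesmoothError):
    """A time or boundary lies outside the signal's span."""


class InvalidWeightsError(KinesmoothError):
    """Weight vector is invalid (negative entries or zero sum)."""


class FormatError(KinesmoothError):
    """An input file does not conform to the expected format."""


class SamplingError(KinesmoothError):
    """Timestamps are too irregular to treat as uniformly sampled."""
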