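"""Exception hierarchy shared across the package.

All errors raised by aostain derive from :class:`AOStainError`, so callers
can catch one base class at pipeline boundaries while tests can still
assert the precise failure mode.
"""


class AOStainError(Exception):
    """Base class for all aostain errors."""


class FormatError(AOStainError):
    """An input file is not in the expected format (e.g. not 8-bit RGB TIFF)."""


class DimensionError(AOStainError):
    """Array shapes or lengths are inconsistent, or dimensions are not even."""


class StateError(AOStainError):
    """An operation was applied in an invalid processing state
    (e.g. dark-subtracting an already dark-subtracted image)."""


class ParameterError(AOStainError, ValueError):
    """A scalar parameter is out of its physical or logical range."""


class DataError(AOStainError):
    """Input data violate a structural precondition
    (e.g. non-monotone titrant volumes, non-positive absorbance)."""


class FitDegeneracyError(AOStainError):
    """A fit cannot resolve the structure it requires
    (e.g. fewer than three titration segments)."""


class EmptyMaskError(AOStainError):
    """A statistic was requested over a mask that retains no pixels."""


class SampleSizeError(AOStainError):
    """Too few replicate observations for the requested statistic."""


class NotDecayingError(AOStainError):
    """A decay fit was requested on a series whose fitted slope is not negative."""
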