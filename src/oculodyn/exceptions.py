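"""Exception hierarchy.

Everything raised on purpose derives from :class:`OculodynError`, so callers
(notably the pipeline, which must skip bad series rather than abort a cohort)
can catch one base class.
"""


class OculodynError(Exception):
    """Base class for all errors raised by oculodyn."""


class InvalidParameterError(OculodynError, ValueError):
    """A parameter value violates its contract (e.g. cutoff >= Nyquist)."""


class TooShortError(OculodynError, ValueError):
    """The input series is too short for the requested operation."""


class DegenerateInputError(OculodynError, ValueError):
    """Input with no usable variation (constant series, zero IQR...)."""


class WindowBoundsError(InvalidParameterError):
    """A window specification falls outside the series bounds."""


class SegmentationError(OculodynError, ValueError):
    """A recording cannot be split as its stimulus schedule demands."""


class InsufficientPairsError(OculodynError, ValueError):
    """Too few admissible point pairs for a neighbour-based estimator."""


class NumericOverflowError(OculodynError, ArithmeticError):
    """A generated trajectory diverged numerically."""
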