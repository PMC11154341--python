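"""Exception hierarchy for pairflow.

All package errors derive from :class:`PairflowError` so callers can catch
everything with one clause; the subclasses distinguish malformed input files,
timing problems, undersized data, and degenerate numerics.
"""


class PairflowError(Exception):
    """Base class for all pairflow errors."""


class FormatError(PairflowError):
    """Input file does not match the expected column layout."""


class TimingError(PairflowError):
    """Time column is non-monotone or not uniformly sampled."""


class InsufficientDataError(PairflowError):
    """Series too short for the requested computation."""


class AlignmentError(PairflowError):
    """Paired series have mismatched lengths."""


class LagRangeError(PairflowError):
    """Requested lag exceeds what the series length supports."""


class ResolutionError(PairflowError):
    """Discretization bit depth outside the supported range."""


class ParameterError(PairflowError):
    """Invalid analysis or simulation parameter."""


class DegenerateInputError(PairflowError):
    """Input has no variance (or is otherwise rank deficient)."""


class GeometryError(PairflowError):
    """Tank geometry parameters are inconsistent."""


class StabilityError(PairflowError):
    """Integration step too large for the requested dynamics."""
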