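"""Exception hierarchy for lithosym.

All package errors derive from :class:`LithosymError` so callers can catch
one base class; subclasses distinguish parse problems from geometric and
statistical degeneracies.
"""


class LithosymError(Exception):
    """Base class for all lithosym errors."""


class ParseError(LithosymError):
    """A file could not be parsed under the declared dialect."""


class DuplicateRecordError(ParseError):
    """The same (artifact_id, view) key occurred more than once."""


class ExtractionError(LithosymError):
    """Contour extraction from a raster mask failed (e.g. empty foreground)."""


class ParameterError(LithosymError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateContourError(LithosymError):
    """A contour has zero size or otherwise degenerate geometry."""


class SelfIntersectionError(LithosymError):
    """A generated or deformed outline crosses itself."""


class UndefinedStatisticError(LithosymError):
    """A statistic is undefined for the given data (e.g. zero variance)."""
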