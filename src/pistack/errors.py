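"""Exception hierarchy for pistack.

All errors raised by the library derive from :class:`PiStackError` so callers
(and the CLI) can catch one base class.
"""


class PiStackError(Exception):
    """Base class for all pistack errors."""


class UnknownTemplateError(PiStackError):
    """Requested monomer template or substituent is not in the registry."""


class InvalidGeometryError(PiStackError):
    """Dimer configuration violates a geometric precondition (e.g. z <= 0)."""


class XYZParseError(PiStackError):
    """Malformed XYZ file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class IncompleteChargeSetError(PiStackError):
    """A monomer atom lacks the sigma/pi charge entry it needs."""


class SingularGeometryError(PiStackError):
    """Coincident inter-molecular sites/atoms make the energy undefined."""


class GuardDistanceError(PiStackError):
    """An inter-atomic distance fell below the exp-6 guard radius."""


class GridAlignmentError(PiStackError):
    """Grids passed to a nodewise operation do not share a lattice."""


class CoverageError(PiStackError):
    """A requested grid does not cover the region a fixture requires."""


class UndefinedCorrelationError(PiStackError):
    """Correlation requested for a zero-variance input."""


class MissingBaselineError(PiStackError):
    """A relative-energy table was requested without the unsubstituted baseline."""
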