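"""Exception hierarchy for metacal.

All metacal-specific failures derive from :class:`MetacalError` so callers can
catch the package's errors with a single except clause.
"""


class MetacalError(Exception):
    """Base class for all metacal errors."""


class InvalidParameterError(MetacalError, ValueError):
    """A parameter is outside its valid domain (e.g. r0 <= 0, radius <= 0)."""


class InvalidInputError(MetacalError, ValueError):
    """Input data violates a precondition (negative distance, non-finite value)."""


class DimensionError(MetacalError, ValueError):
    """Mismatched shapes / incompatible contact selections."""


class NormalizationError(MetacalError, ValueError):
    """A probability histogram does not sum to one."""


class InsufficientDataError(MetacalError, ValueError):
    """Too few frames/samples for the requested operation."""


class InvalidPathError(MetacalError, ValueError):
    """A node path is malformed (repeated nodes, empty path)."""

class InvalidBlockError(MetacalError, ValueError):
    """Variable blocks overlap or reference missing columns."""


class DegenerateInputError(MetacalError, ValueError):
    """Input has no variance / is otherwise degenerate for the operation."""


class ConvergenceError(MetacalError, RuntimeError):
    """An iterative solver failed to reach tolerance.

    Attributes
    ----------
    residuals : dict | None
        Final constraint residuals, when available.
    """

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class InfeasibleConstraintError(MetacalError, ValueError):
    """Requested constraint targets cannot be met by the model family."""


class UnreachableTargetError(MetacalError, ValueError):
    """MFPT target set is unreachable from a source state."""


class AmbiguousRegionError(MetacalError, ValueError):
    """Region boxes overlap so state assignment is ambiguous."""


class EmptyRegionError(MetacalError, ValueError):
    """A region contains no microstates."""


class ParseError(MetacalError, ValueError):
    """Malformed COLVAR/HILLS/config file.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message, line_number=None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class StabilityError(MetacalError, RuntimeError):
    """An integrator step diverged; try a smaller time step."""
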