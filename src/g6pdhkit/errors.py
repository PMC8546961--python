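"""Exception hierarchy shared across the package."""


class G6pdhkitError(Exception):
    """Base class for all package errors."""


class ParameterError(G6pdhkitError):
    """A kinetic constant is missing, nonpositive or otherwise invalid."""


class InputError(G6pdhkitError):
    """User-supplied data violates a precondition (negative concentration,
    ragged arrays, empty sequence, ...)."""


class UsageError(G6pdhkitError):
    """An API call is malformed (unknown mode, empty candidate list, ...)."""


class InsufficientDataError(G6pdhkitError):
    """Too few usable observations for the requested estimate."""


class EstimationError(G6pdhkitError):
    """A closed-form estimator is degenerate on the given data."""


class ConvergenceError(G6pdhkitError):
    """No optimizer start converged; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class InsufficientOverlapError(G6pdhkitError):
    """Curves do not share a common rescaled-time range."""


class ValidationError(G6pdhkitError):
    """A run configuration fails schema validation."""
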