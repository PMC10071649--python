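"""Exception and warning types used across the package."""


class InvalidInputError(ValueError):
    """Raised when input data or options violate a documented precondition."""


class NumericalError(RuntimeError):
    """Raised when an update becomes numerically undefined (e.g. a zero
    denominator in the baseline-jump update at a named grid point)."""


class ConvergenceWarning(UserWarning):
    """Emitted when an iterative procedure stops without meeting its
    convergence criterion, or takes a guarded fallback step."""


class DegenerateDataWarning(UserWarning):
    """Emitted when data are valid but degenerate for the requested
    computation (single subject pairwise term, zero interval mass, ...)."""
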