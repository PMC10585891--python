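"""Exception hierarchy."""


class CapcaError(Exception):
    """Base class for all package-specific errors."""


class LexisValidationError(CapcaError, ValueError):
    """Raised when a rate table or grid violates a structural invariant."""


class ConvergenceError(CapcaError, RuntimeError):
    """Raised when a Poisson fit fails to converge or the data are degenerate."""
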