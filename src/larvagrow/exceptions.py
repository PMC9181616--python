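"""Exception types shared across the package."""


class LarvagrowError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(LarvagrowError, ValueError):
    """An input value violates a documented precondition."""


class FitConvergenceError(LarvagrowError, RuntimeError):
    """No start point of a multi-start fit converged.

    Carries per-start diagnostics in ``diagnostics`` (list of strings).
    """

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = list(diagnostics or [])


class NonIdentifiableError(LarvagrowError, RuntimeError):
    """The Jacobian at the solution is singular; standard errors undefined."""
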