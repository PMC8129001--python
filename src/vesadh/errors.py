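"""Exception hierarchy."""


class VesadhError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(VesadhError, ValueError):
    """A physical parameter is out of its admissible range."""


class ConfigurationError(VesadhError, ValueError):
    """A configuration is internally inconsistent (e.g. P*dt > 1)."""


class InvalidShapeError(VesadhError, ValueError):
    """A shape mesh violates its geometric invariants."""


class SolverError(VesadhError, RuntimeError):
    """An iterative solver failed to converge; carries the last residual."""

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


class FitFailureError(VesadhError, RuntimeError):
    """A least-squares fit did not converge or left large residuals."""

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


class CoverageDomainError(VesadhError, ValueError):
    """A (rho, eta) pair is geometrically impossible."""
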