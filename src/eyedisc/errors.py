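"""Exception types shared across the package."""


class EyeDiscError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgument(EyeDiscError, ValueError):
    """An argument violates a documented precondition."""


class InvalidState(EyeDiscError, ValueError):
    """A field state violates a model invariant (e.g. negative concentration)."""


class ConfigurationRejected(EyeDiscError, ValueError):
    """A parameter set violates a construction-time invariant."""


class ShapeIncompatible(EyeDiscError, ValueError):
    """Fields defined on different meshes were combined."""


class InsufficientData(EyeDiscError, ValueError):
    """Too few valid data points for an estimation procedure."""


class SolverFailure(EyeDiscError, RuntimeError):
    """A linear or nonlinear solve did not converge; carries diagnostics."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class GeometryError(EyeDiscError, RuntimeError):
    """Fatal mesh geometry problem (inverted elements, self-intersection)."""


class NoRecovery(EyeDiscError, ValueError):
    """A FRAP recovery curve never reaches its half-recovery level."""
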