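"""Exception types shared across the pipeline stages."""


class StimmapError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(StimmapError):
    """Invalid or inconsistent spatial configuration (radii, electrode placement, ...)."""


class ConfigurationError(StimmapError):
    """Missing or invalid configuration entry (e.g. a tissue label without a conductivity)."""


class SolverError(StimmapError):
    """Iterative solver failed to reach the requested residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class FrameMismatchError(StimmapError):
    """Two spatial objects do not share a coordinate frame."""


class EmptyInputError(StimmapError):
    """An operation that needs a non-empty input received an empty one."""


class DegenerateWeightError(StimmapError):
    """All weights vanished where a weighted reduction was requested."""


class UndefinedOverlapError(StimmapError):
    """The overlap denominator (supra-threshold nTMS area) has zero area."""


class InsufficientDataError(StimmapError):
    """Fewer samples than the statistic requires."""


class DegenerateDataError(StimmapError):
    """Zero-variance data where a test statistic is undefined."""
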