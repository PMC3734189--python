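"""Exception hierarchy shared across the package."""


class AqvtError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(AqvtError):
    """An input violates a documented precondition."""


class ShapeError(ValidationError):
    """Dimension mismatch between geometric objects."""


class DegenerateGeometryError(ValidationError):
    """Point set does not affinely span the requested dimension."""

    def __init__(self, message: str, deficient_dims: int = 0):
        super().__init__(message)
        self.deficient_dims = deficient_dims


class ConvergenceError(AqvtError):
    """Iterative solver failed to reach tolerance within its iteration cap."""

    def __init__(self, message: str, achieved_tol: float = float("nan")):
        super().__init__(message)
        self.achieved_tol = achieved_tol


class ConditioningError(AqvtError):
    """Linear system is singular or too ill-conditioned to solve reliably."""


class PackingError(AqvtError):
    """Could not place the requested number of sites in the domain."""


class ParseError(AqvtError):
    """Malformed input file."""
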