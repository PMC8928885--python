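"""Named exceptions and warnings shared across the package."""


class PtarmiganError(Exception):
    """Base class for package errors."""


class ValidationError(PtarmiganError, ValueError):
    """Invalid input: out-of-range parameters, malformed tables, bad shapes."""


class DegenerateGeometryError(PtarmiganError):
    """Point set has no 2-D extent (e.g. all points collinear).

    Carries the degenerate area (0.0) in ``area_km2`` so callers that can
    tolerate zero-area ranges may recover it.
    """

    def __init__(self, message: str, area_km2: float = 0.0):
        super().__init__(message)
        self.area_km2 = area_km2


class ConvergenceError(PtarmiganError, RuntimeError):
    """An iterative fit failed to converge; ``diagnostics`` holds details."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SeparationWarning(UserWarning):
    """Complete or quasi-complete separation detected in a binomial fit."""
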