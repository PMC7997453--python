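"""Exception hierarchy shared across the package."""


class CypddiError(Exception):
    """Base class for all package-specific errors."""


class DesignError(CypddiError):
    """An assay design violates its structural requirements (grids, replicates)."""


class DataError(CypddiError):
    """An observation table is malformed or contains inadmissible values."""


class FitError(CypddiError):
    """An estimator failed to converge or produced an inadmissible estimate.

    Carries optional residual diagnostics in ``diagnostics``.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DomainError(CypddiError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ConfigurationError(CypddiError):
    """A simulation configuration is inconsistent or incomplete."""


class SolverError(CypddiError):
    """ODE integration failed; ``state`` holds the last solver state for debugging."""

    def __init__(self, message: str, state: dict | None = None):
        super().__init__(message)
        self.state = state or {}
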