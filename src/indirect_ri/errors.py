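"""Exception hierarchy shared across the package."""


class IndirectRIError(Exception):
    """Base class for all package-specific errors."""


class DomainError(IndirectRIError, ValueError):
    """Input outside the mathematical domain of an operation."""


class ConfigurationError(IndirectRIError):
    """Invalid configuration (missing column, bad bounds, ...)."""


class EmptyInputError(IndirectRIError):
    """No rows survived reading/filtering."""


class InsufficientDataError(IndirectRIError):
    """Too few observations for the requested fit."""


class FitError(IndirectRIError):
    """A model fit failed (degenerate data, non-monotone plot, ...)."""


class ConvergenceError(FitError):
    """An iterative fit did not converge within tolerance."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class GenerationError(IndirectRIError):
    """Synthetic-data generation could not produce valid draws."""


class CIError(IndirectRIError):
    """Bootstrap confidence-interval computation failed."""


class ReportError(IndirectRIError):
    """All estimators failed; no comparison report can be built."""
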