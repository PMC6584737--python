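"""Exception hierarchy for the analysis pipeline."""


class VwmError(Exception):
    """Base class for all package errors."""


class SchemaError(VwmError):
    """A CSV/JSON input violates the documented schema (names row/column)."""


class ConfigError(VwmError):
    """An invalid cohort spec or analysis configuration."""


class EstimationError(VwmError):
    """A summary statistic cannot be computed from the given trials."""


class FitError(VwmError):
    """Mixture-model optimisation failed on every start."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DesignError(VwmError):
    """An ANOVA design is unbalanced or has missing cells."""
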