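"""Exception hierarchy shared across the package."""


class MatPpmError(Exception):
    """Base class for all package-specific errors."""


class DataError(MatPpmError):
    """A dataset violates a structural precondition (empty, overlapping cohorts, ...)."""


class MissingDataError(DataError):
    """A required field or observation is absent. No imputation is ever attempted."""


class SchemaError(DataError):
    """A table or code does not conform to the declared schema / taxonomy."""


class InvalidExposureError(DataError):
    """A subtask exposure with zero presentations cannot define a proportion."""


class InconsistentCountsError(DataError):
    """Failure count exceeds presentation count (or counts are negative)."""


class ParameterError(MatPpmError):
    """An argument is outside its documented domain (e.g. m outside (0, 1])."""


class StateError(MatPpmError):
    """An object is used before it was fitted / initialised."""


class UndefinedSimilarityError(MatPpmError):
    """Cosine similarity requested for a zero vector — never silently 0."""


class FitError(MatPpmError):
    """Model fitting failed and no fallback was permitted."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ConfigError(MatPpmError):
    """A configuration object is internally inconsistent or infeasible."""
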