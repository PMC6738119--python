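"""Exception hierarchy shared across the pipeline."""


class InvigorError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(InvigorError):
    """Cohort file does not match the canonical column schema."""


class ParseError(InvigorError):
    """A cell could not be parsed into its declared type."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        super().__init__(message)
        self.row = row
        self.column = column


class DomainError(InvigorError, ValueError):
    """Mathematically invalid input to a growth/geometry primitive."""


class DataError(InvigorError):
    """Cohort content is unusable for the requested analysis stage."""


class ConvergenceError(InvigorError):
    """A model fit failed to converge; carries fitter diagnostics."""


class PipelineStageError(InvigorError):
    """Wraps an error with the pipeline stage in which it occurred."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original
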