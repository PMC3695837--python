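"""Exception hierarchy shared across the pipeline."""


class EnvPathError(Exception):
    """Base class for all pipeline errors."""


class FormatError(EnvPathError):
    """A malformed input file.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigError(EnvPathError):
    """An invalid parameters-file entry or threshold value."""


class AnnotationError(EnvPathError):
    """A hit table inconsistent with its self-score table."""


class CatalogError(EnvPathError):
    """An invalid pathway-catalog entry."""


class PipelineError(EnvPathError):
    """A stage-level orchestration failure (missing prerequisite etc.)."""
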