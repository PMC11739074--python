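"""Exception hierarchy.

Validation problems (bad config, malformed input files) raise
:class:`ValidationError`; failures inside a pipeline stage are wrapped in
:class:`StageError` with the stage name attached.
"""


class StageMirrorError(Exception):
    """Base class for all package errors."""


class ValidationError(StageMirrorError):
    """Invalid configuration or input data."""


class ConfigError(ValidationError):
    """A configuration field is out of range; names the field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field {field!r}: {message}")


class ParseError(ValidationError):
    """Malformed input file; carries file and line where known."""

    def __init__(self, path, line: int | None, message: str):
        self.path = str(path)
        self.line = line
        loc = f"{path}:{line}" if line is not None else str(path)
        super().__init__(f"{loc}: {message}")


class GenerationError(StageMirrorError):
    """The synthetic-data generator cannot realize the requested truth."""


class UndefinedCorrelationError(StageMirrorError):
    """A correlation is requested on a zero-variance vector."""


class StageError(StageMirrorError):
    """A pipeline stage failed; upstream outputs are preserved."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
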