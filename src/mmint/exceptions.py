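"""Exception hierarchy shared across the pipeline stages."""


class MMIntError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MMIntError):
    """A configuration value or source registry entry is invalid or missing."""


class ValidationError(MMIntError):
    """An input object violates a documented precondition."""


class NormalizationError(ValidationError):
    """Size-factor estimation is impossible for the given count matrix."""


class InsufficientDataError(ValidationError):
    """Too few observations for the requested statistic."""


class StageError(MMIntError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
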