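"""Exception hierarchy shared across the pipeline."""


class BivalinkError(Exception):
    """Base class for all pipeline errors."""


class FormatError(BivalinkError, ValueError):
    """A file does not conform to its expected dialect."""


class ConfigError(BivalinkError, ValueError):
    """Inconsistent or impossible configuration."""


class DegenerateNormalizationError(BivalinkError, ValueError):
    """Saturated signal value is zero; scale factors are undefined."""


class CalibrationError(BivalinkError, ValueError):
    """Threshold calibration target cannot be satisfied."""


class UniverseMismatchError(BivalinkError, ValueError):
    """Two per-gene structures do not share the same gene universe."""


class PipelineError(BivalinkError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {message}")
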