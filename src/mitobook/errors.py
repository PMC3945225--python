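"""Exception hierarchy shared across the pipeline."""


class MitobookError(Exception):
    """Base class for all package errors."""


class ConfigError(MitobookError):
    """Invalid configuration value."""


class SizingError(ConfigError):
    """A chromosome is too short to host the requested features."""


class PlacementError(MitobookError):
    """Requested sites cannot be placed at the configured minimum spacing."""


class FormatError(MitobookError):
    """Malformed input file.

    Carries the 1-based line number of the first offending line when known.
    """

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)


class StageError(MitobookError):
    """A pipeline stage failed; names the stage for the operator."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")
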