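"""Exception hierarchy shared across the pipeline."""


class MadetectError(Exception):
    """Base class for all package-specific errors."""


class ChannelError(MadetectError):
    """Raised when an image does not carry the three RGB channels."""


class AnnotationParseError(MadetectError):
    """Raised on a malformed annotation/detection row; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DegenerateInputError(MadetectError):
    """Raised when an input has no exploitable structure (e.g. constant image)."""


class ShapeError(MadetectError):
    """Raised on incompatible array shapes."""


class ConfigError(MadetectError):
    """Raised when configuration values violate their invariants."""


class ModelMismatchError(MadetectError):
    """Raised when a trained model is incompatible with the requested config."""
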