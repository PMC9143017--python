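"""Exception hierarchy shared across the package."""


class TurbispecError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(TurbispecError, ValueError):
    """A parameter violates a documented precondition."""


class RangeError(TurbispecError, ValueError):
    """A wavelength or window falls outside the available grid."""


class DegenerateInputError(TurbispecError, ValueError):
    """Input is formally valid but carries no usable information."""


class ConfigurationError(TurbispecError, ValueError):
    """A design/config document is inconsistent."""


class ParseError(TurbispecError, ValueError):
    """A file could not be parsed; message names the offending line."""


class StageError(TurbispecError, RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
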