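"""Exception hierarchy shared across the package."""


class RCGError(Exception):
    """Base class for all simulator errors."""


class ConfigurationError(RCGError, ValueError):
    """Invalid model parameters, graph construction arguments, or CLI input."""


class StateError(RCGError, RuntimeError):
    """Operation applied to a population in an unusable state (empty, bad index)."""


class EdgeListError(RCGError, ValueError):
    """Malformed edge-list file.  Carries the offending 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class UndefinedRatioError(RCGError, RuntimeError):
    """A ratio diagnostic has an empty class or a zero denominator."""
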