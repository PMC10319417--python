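"""Exception types shared across the toolkit."""


class LmbciError(Exception):
    """Base class for package errors."""


class ConfigError(LmbciError, ValueError):
    """Invalid simulation or pipeline configuration."""


class InsufficientTrialsError(LmbciError, ValueError):
    """Fewer clean trials available than requested for a condition."""

    def __init__(self, condition: str, available: int, requested: int):
        self.condition = condition
        self.available = available
        self.requested = requested
        super().__init__(
            f"condition {condition!r}: {available} clean trials available, "
            f"{requested} requested"
        )


class DegenerateInputError(LmbciError, ValueError):
    """Input is degenerate for the requested computation (e.g. zero baseline power)."""
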