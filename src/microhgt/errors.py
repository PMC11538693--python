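"""Exception hierarchy shared across the package."""


class MicrohgtError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MicrohgtError, ValueError):
    """Malformed input file (non-numeric cell, bad token, missing column)."""


class ValidationError(MicrohgtError, ValueError):
    """Structurally valid input that violates a domain invariant."""


class ConfigError(MicrohgtError, ValueError):
    """Invalid configuration value."""


class TrainingError(MicrohgtError, RuntimeError):
    """Optimization failure (divergence, NaN loss)."""
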