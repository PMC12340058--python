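"""Exception hierarchy for the footgait pipeline."""


class FootgaitError(Exception):
    """Base class for all footgait errors."""


class FormatError(FootgaitError):
    """A file does not match the declared dialect (missing columns, bad header)."""


class DataError(FootgaitError):
    """Parsed data violate a contract (non-monotone time, too short, not quiescent)."""


class ConfigError(FootgaitError):
    """Invalid configuration values (unknown units, bad correlation matrix)."""


class ValidationError(FootgaitError):
    """A record fails a field-level validation rule."""


class NoGaitError(DataError):
    """No qualifying mid-swing angular-velocity peak was found."""
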