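"""Exception types shared across the package."""


class TrialTrackError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TrialTrackError, ValueError):
    """A configuration value is invalid (unknown dialect, bad window, unknown rule)."""


class SchemaError(TrialTrackError, ValueError):
    """An input file violates the expected schema (missing column, unknown label)."""


class ContractError(TrialTrackError, ValueError):
    """A cross-object precondition is violated (mixed source orders, >2 raters)."""
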