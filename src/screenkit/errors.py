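"""Exception hierarchy shared across the package."""


class ScreenKitError(Exception):
    """Base class for all screenkit errors."""


class InvalidParameterError(ScreenKitError, ValueError):
    """A parameter is out of its allowed domain."""


class FormatError(ScreenKitError, ValueError):
    """An input file does not match the expected layout."""


class ConsistencyError(ScreenKitError, ValueError):
    """Inputs disagree with each other (e.g. a guide absent from the library)."""


class ConfigError(ScreenKitError, ValueError):
    """A run configuration is invalid; the message names the offending key."""


class BudgetError(ScreenKitError, RuntimeError):
    """A requested computation exceeds the configured size budget."""
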