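"""Exception hierarchy shared across the package."""


class TSMLError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(TSMLError, ValueError):
    """A data argument violates a precondition (shape, finiteness, range)."""


class ConfigurationError(TSMLError, ValueError):
    """A configuration value is out of range or names an unknown component."""
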