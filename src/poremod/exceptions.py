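"""Exception hierarchy shared across the package."""


class PoremodError(Exception):
    """Base class for all errors raised by poremod."""


class ConfigurationError(PoremodError):
    """A configuration value is missing, out of range, or inconsistent."""


class FormatError(PoremodError):
    """An input file does not conform to its declared dialect."""


class ValidationError(PoremodError):
    """Well-formed input violates a semantic invariant."""


class UndefinedMetricError(PoremodError):
    """A metric is requested on input where it is mathematically undefined."""
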