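"""Exception hierarchy.

ConfigurationError maps to CLI exit code 2, DataError to exit code 3.
"""


class GenovalError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GenovalError):
    """Invalid configuration value or inconsistent options."""


class DataError(GenovalError):
    """Malformed, inconsistent, or degenerate input data."""
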