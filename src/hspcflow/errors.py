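"""Exception hierarchy.

``ConfigError`` covers invalid parameters/configuration (CLI exit code 2);
everything else derived from :class:`HspcflowError` is a runtime failure
(exit code 1).
"""


class HspcflowError(Exception):
    """Base class for all package errors."""


class ConfigError(HspcflowError):
    """Invalid configuration or parameter values."""


class DataError(HspcflowError):
    """Malformed or inconsistent input data."""


class EmptyResultError(HspcflowError):
    """An operation removed every cell (or produced an empty result)."""
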