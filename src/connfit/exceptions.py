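"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class ConnfitError(Exception):
    """Base class for all package errors."""


class ConfigError(ConnfitError, ValueError):
    """Invalid configuration: bad parameter values, impossible sizing."""


class DataError(ConnfitError, ValueError):
    """Invalid data: shape mismatches, zero variance, non-finite values."""
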