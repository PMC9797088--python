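"""Exception hierarchy shared across the package.

``ConfigError`` maps to CLI exit code 2 and ``DataError`` to exit code 3.
"""


class ForestnetError(Exception):
    """Base class for all package errors."""


class ConfigError(ForestnetError):
    """Invalid parameters, unknown dialects, malformed configuration."""


class DataError(ForestnetError):
    """Problems with input data or model/data compatibility."""


class ParseError(DataError):
    """A model dump or table could not be parsed."""
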