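"""Exception hierarchy.

Split along the CLI's exit-code contract: configuration/usage problems
(exit 1) versus malformed or inconsistent input data (exit 2).
"""


class ExtufailError(Exception):
    """Base class for all package errors."""


class ConfigError(ExtufailError):
    """Invalid configuration: bad scenario mix, impossible prevalence, bad paths."""


class DataError(ExtufailError):
    """Input data violates the format or consistency contract."""


class FlowsheetParseError(DataError):
    """A flow-sheet or metadata CSV could not be parsed; names the offending row."""
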