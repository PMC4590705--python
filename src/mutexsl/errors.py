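"""Exception hierarchy shared across the package.

Each error class carries the process exit code the CLI maps it to.
"""


class MutexSLError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(MutexSLError):
    """Invalid configuration or argument values."""

    exit_code = 2


class ParseError(MutexSLError):
    """Malformed input file (structure or cell contents)."""

    exit_code = 3


class DataValidationError(MutexSLError):
    """Structurally valid input that violates a domain invariant."""

    exit_code = 4


class GeneLookupError(DataValidationError):
    """A requested gene or cell line is absent from the data."""
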