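"""Exception hierarchy shared across the pipeline.

``DataError`` covers malformed or inconsistent inputs (exit code 1 in the
CLI); ``ConfigError`` covers invalid run configuration (exit code 2).
"""


class EdnaClockError(Exception):
    """Base class for all package errors."""


class DataError(EdnaClockError):
    """Malformed or internally inconsistent input data."""


class BedMethylParseError(DataError):
    """A bedMethyl row could not be parsed."""


class GenBankFormatError(DataError):
    """The GenBank flat file lacks a usable FEATURES table."""


class ClockSerializationError(DataError):
    """A clock JSON file is truncated, corrupt, or of a wrong version."""


class ConfigError(EdnaClockError):
    """Invalid run configuration."""
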