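"""Exception hierarchy shared across the package."""


class RefugiaError(Exception):
    """Base class for all package errors."""


class ConfigError(RefugiaError):
    """Invalid configuration (unknown keys, bad bounds, missing paths)."""


class DataError(RefugiaError):
    """Invalid or insufficient input data."""


class AlignmentError(DataError):
    """Ragged alignment or mismatched alignment shapes."""


class FormatError(DataError):
    """Illegal characters or malformed file contents."""


class InsufficientDataError(DataError):
    """An operation's minimum sample-size or polymorphism requirement is unmet."""


class NumericalError(RefugiaError):
    """A numerical routine failed to converge or produced invalid output."""
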