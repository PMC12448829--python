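"""Exception hierarchy shared across the package.

The CLI maps these to distinct exit codes: ConfigError -> 2,
DataError -> 3, anything else -> 4.
"""


class ProtfunError(Exception):
    """Base class for package errors."""


class ConfigError(ProtfunError):
    """Invalid configuration (bad parameter values, inconsistent dims)."""


class DataError(ProtfunError):
    """Malformed or inconsistent input data (files, tables, graphs)."""


class FormatError(DataError):
    """A file does not conform to its declared format."""


class EmbeddingError(ProtfunError):
    """The embedder adapter failed for a sequence."""
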