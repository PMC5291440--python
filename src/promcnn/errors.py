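"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: configuration/parse problems -> 2,
data problems -> 3, anything else -> 4.
"""


class PromcnnError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PromcnnError):
    """Invalid configuration: bad architecture string, motif outside window, ..."""


class DataError(PromcnnError):
    """Invalid data: malformed FASTA, alphabet violations, length mismatches, ..."""


class UndefinedMetricError(PromcnnError):
    """A performance measure is undefined for the given confusion counts."""


class ModelIOError(PromcnnError):
    """A model file could not be read or fails its integrity checks."""
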