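"""Exception hierarchy shared across the package."""


class VirnaError(Exception):
    """Base class for all package errors."""


class AlphabetError(VirnaError):
    """Sequence contains characters outside the expected alphabet."""


class InputError(VirnaError):
    """Structurally invalid input (empty sequence, bad shape, ...)."""


class ConfigError(VirnaError):
    """Invalid configuration value."""


class FormatError(VirnaError):
    """Malformed file content (FASTQ/FASTA/newick)."""


class DataError(VirnaError):
    """Data values that make an analysis undefined (e.g. a sequence
    pair with no comparable alignment columns)."""


class ConsistencyError(VirnaError):
    """Internally inconsistent objects passed together (e.g. a hit
    outside the bounds of its reference segment)."""


class GenerationError(VirnaError):
    """Synthetic-data generation could not satisfy its constraints."""
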