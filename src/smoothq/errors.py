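"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes (usage 2, input format 3,
index format 4), so keep input-format and index-format errors separate.
"""


class SmoothqError(Exception):
    """Base class for all package errors."""


class FormatError(SmoothqError):
    """Malformed input data (generic)."""


class FastaFormatError(FormatError):
    """Malformed FASTA input (bad symbol, empty file, ...)."""


class FastqFormatError(FormatError):
    """Malformed FASTQ input; message carries the 1-based record number."""


class IndexFormatError(SmoothqError):
    """Corrupted, truncated or version-mismatched index file."""


class CapacityError(SmoothqError):
    """Input exceeds the configured in-memory build capacity."""
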