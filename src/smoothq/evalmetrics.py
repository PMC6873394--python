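"""Effect measurement: quality-stream entropy and compression ratios.

Smoothing is justified by compressibility, so the primary instrument here
is the ratio achieved by standard general-purpose compressors
(ratio = uncompressed size / compressed size); order-0 Shannon entropy of
the quality stream and the distinct-symbol count are diagnostics.
"""

from __future__ import annotations

import bz2
import gzip
import lzma
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .errors import FastqFormatError
from .fastq_io import ReadRecord, stream_fastq

#: supported compressors: callable and the (default) level it runs at
_COMPRESSORS = {
    "gzip": (lambda b: gzip.compress(b), "9"),
    "bzip2": (lambda b: bz2.compress(b), "9"),
    "lzma": (lambda b: lzma.compress(b), "preset-6"),
}


@dataclass
class CompressionSummary:
    uncompressed_bytes: int
    compressed_bytes: int
    ratio: float  # uncompressed / compressed
    compressor_name: str
    compressor_level: str
    entropy_bits_per_symbol: float | None
    distinct_quality_symbols: int | None

    def as_tsv(self) -> str:
        ent = (
            f"{self.entropy_bits_per_symbol:.4f}"
            if self.entropy_bits_per_symbol is not None
            else "NA"
        )
        dqs = (
            str(self.distinct_quality_symbols)
            if self.distinct_quality_symbols is not None
            else "NA"
        )
        return "\n".join(
            [
                f"compressor\t{self.compressor_name} (level {self.compressor_level})",
                f"uncompressed_bytes\t{self.uncompressed_bytes}",
                f"compressed_bytes\t{self.compressed_bytes}",
                f"ratio\t{self.ratio:.4f}",
                f"quality_entropy_bits\t{ent}",
                f"distinct_quality_symbols\t{dqs}",
            ]
        )


def _entropy_from_counts(counts: Counter) -> float:
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no quality symbols")
    ent = 0.0
    for c in counts.values():
        p = c / total
        ent -= p * math.log2(p)
    return ent


def quality_entropy(records: Iterable[ReadRecord]) -> float:
    """Order-0 Shannon entropy (bits/symbol) of the concatenated quality
    stream of the records."""
    counts: Counter = Counter()
    any_record = False
    for rec in records:
        any_record = True
        counts.update(rec.quality)
    if not any_record:
        raise ValueError("at least one record required")
    return _entropy_from_counts(counts)


def compression_ratio(path: str | Path, compressor: str = "gzip") -> CompressionSummary:
    """Compress the raw bytes of ``path`` and report the size ratio.

    If the file parses as FASTQ, the quality-stream entropy and distinct
    quality symbol count are included as diagnostics; otherwise those
    fields are None.
    """
    if compressor not in _COMPRESSORS:
        raise ValueError(
            f"unsupported compressor {compressor!r}; "
            f"choose from {sorted(_COMPRESSORS)}"
        )
    raw = Path(path).read_bytes()
    fn, level = _COMPRESSORS[compressor]
    compressed = fn(raw)

    entropy: float | None = None
    distinct: int | None = None
    try:
        counts: Counter = Counter()
        for rec in stream_fastq(path, allow_suspect_encoding=True):
            counts.update(rec.quality)
        if counts:
            entropy = _entropy_from_counts(counts)
            distinct = len(counts)
    except (FastqFormatError, UnicodeDecodeError, OSError):
        pass  # not FASTQ (or not text): entropy diagnostics unavailable

    return CompressionSummary(
        uncompressed_bytes=len(raw),
        compressed_bytes=len(compressed),
        ratio=len(raw) / len(compressed) if compressed else float("inf"),
        compressor_name=compressor,
        compressor_level=level,
        entropy_bits_per_symbol=entropy,
        distinct_quality_symbols=distinct,
    )


@dataclass
class FidelitySummary:
    """How smoothing treated the qualities at true error positions."""

    error_positions_total: int
    kept: int  # quality unchanged
    raised: int  # quality changed (replacement applied)

    @property
    def kept_fraction(self) -> float:
        if self.error_positions_total == 0:
            return 1.0
        return self.kept / self.error_positions_total


def smoothing_fidelity(
    truth_path: str | Path,
    original_fastq: str | Path,
    smoothed_fastq: str | Path,
) -> FidelitySummary:
    """Count error-position qualities kept vs raised by smoothing.

    All three files must be row-aligned on the same reads; an identifier
    mismatch raises ValueError.
    """
    from .simdata import read_truth  # local import to avoid a cycle

    truth = read_truth(truth_path)
    total = kept = raised = 0
    orig_iter = stream_fastq(original_fastq)
    smooth_iter = stream_fastq(smoothed_fastq)
    for (rid, _off, _strand, errs), orig, smo in zip(truth, orig_iter, smooth_iter):
        if orig.header.split()[0] != rid or smo.header.split()[0] != rid:
            raise ValueError(
                f"id mismatch: truth {rid!r} vs FASTQ "
                f"{orig.header!r}/{smo.header!r}"
            )
        for p in errs:
            total += 1
            if smo.quality[p] == orig.quality[p]:
                kept += 1
            else:
                raised += 1
    return FidelitySummary(error_positions_total=total, kept=kept, raised=raised)
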