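"""Streaming FASTQ/FASTA input and output.

FASTQ records are streamed one at a time (memory bounded per record, never
per file), in file order, preserving every non-quality field byte-for-byte.
Only strict 4-line FASTQ is accepted; wrapped multi-line records are
rejected because they cannot be streamed deterministically.  Inputs may be
plain or gzip-compressed (detected by magic bytes), and the path ``"-"``
denotes the standard streams so the tool composes with shell pipes.

Quality strings are Phred+33.  A quality character above code point 104
strongly suggests a legacy Phred+64 file; such input is rejected unless the
caller explicitly overrides.
"""

from __future__ import annotations

import gzip
import io
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO

from .errors import FastaFormatError, FastqFormatError
from .fmindex import DNA, SEPARATOR, TERMINATOR, Reference

PHRED_OFFSET = 33
_SUSPECT_PHRED64_CODE = 104  # 'h' == Phred+64 quality 40

_VALID_BASES = set(DNA + "N" + DNA.lower() + "n")


@dataclass
class ReadRecord:
    """One FASTQ record.

    ``header`` is the identifier line without the leading ``@``;
    ``separator`` is the ``+`` line verbatim; ``sequence`` keeps the
    original case (smoothing uppercases internally and never alters it).
    """

    header: str
    sequence: str
    separator: str
    quality: str

    def validate(self) -> None:
        if not self.sequence:
            raise FastqFormatError("empty sequence")
        if len(self.sequence) != len(self.quality):
            raise FastqFormatError(
                f"sequence length {len(self.sequence)} != quality length "
                f"{len(self.quality)}"
            )
        if any(not (33 <= ord(c) <= 126) for c in self.quality):
            raise FastqFormatError("quality character outside printable Phred+33 range")

    def quality_values(self) -> list[int]:
        """Phred integers decoded from the quality string."""
        return [ord(c) - PHRED_OFFSET for c in self.quality]


def _binary_reader(source: str | Path | IO) -> tuple[io.BufferedReader, bool]:
    """Return a peekable binary reader and whether we own (must close) it."""
    if isinstance(source, (str, Path)):
        if str(source) == "-":
            return sys.stdin.buffer, False
        return open(source, "rb"), True
    if isinstance(source, io.TextIOBase):
        raise TypeError("pass a binary stream, a path, or '-'")
    if hasattr(source, "peek"):
        return source, False
    return io.BufferedReader(source), False


def _open_text_source(source: str | Path | IO) -> tuple[IO[str], "callable"]:
    """Open a text reader over ``source``, transparently gunzipping.

    Returns the reader and a cleanup callable that closes only what this
    module opened, never a stream owned by the caller.
    """
    if isinstance(source, io.TextIOBase):
        return source, lambda: None
    raw, own = _binary_reader(source)
    if raw.peek(2)[:2] == b"\x1f\x8b":
        gz = gzip.GzipFile(fileobj=raw, mode="rb")
        fh = io.TextIOWrapper(gz)

        def cleanup() -> None:
            fh.detach()
            gz.close()
            if own:
                raw.close()

        return fh, cleanup
    fh = io.TextIOWrapper(raw)

    def cleanup() -> None:
        fh.detach()
        if own:
            raw.close()

    return fh, cleanup


def _open_text_sink(sink: str | Path | IO, gzip_output: bool) -> tuple[IO[str], "callable"]:
    if isinstance(sink, io.TextIOBase):
        return sink, sink.flush
    if isinstance(sink, (str, Path)):
        if str(sink) == "-":
            raw, own = sys.stdout.buffer, False
        else:
            raw, own = open(sink, "wb"), True
            gzip_output = gzip_output or str(sink).endswith(".gz")
    else:
        raw, own = sink, False
    if gzip_output:
        gz = gzip.GzipFile(fileobj=raw, mode="wb")
        fh = io.TextIOWrapper(gz, newline="\n")

        def cleanup() -> None:
            fh.flush()
            fh.detach()
            gz.close()  # writes the gzip trailer; leaves raw open
            if own:
                raw.close()

        return fh, cleanup
    fh = io.TextIOWrapper(raw, newline="\n")

    def cleanup() -> None:
        fh.flush()
        fh.detach()
        if own:
            raw.close()

    return fh, cleanup


def stream_fastq(
    source: str | Path | IO,
    *,
    allow_suspect_encoding: bool = False,
) -> Iterator[ReadRecord]:
    """Yield :class:`ReadRecord` objects in file order.

    Malformed records raise :class:`FastqFormatError` naming the 1-based
    record number; a truncated final record is an error, never silently
    dropped.
    """
    fh, cleanup = _open_text_source(source)
    recno = 0
    try:
        while True:
            header = fh.readline()
            if not header:
                break
            recno += 1
            seq = fh.readline()
            sep = fh.readline()
            qual = fh.readline()
            if not qual:
                raise FastqFormatError(f"record {recno}: truncated record")
            header = header.rstrip("\r\n")
            seq = seq.rstrip("\r\n")
            sep = sep.rstrip("\r\n")
            qual = qual.rstrip("\r\n")
            if not header.startswith("@"):
                raise FastqFormatError(
                    f"record {recno}: header does not start with '@' "
                    "(multi-line records are not supported)"
                )
            if not sep.startswith("+"):
                raise FastqFormatError(
                    f"record {recno}: separator line does not start with '+' "
                    "(multi-line records are not supported)"
                )
            if not seq:
                raise FastqFormatError(f"record {recno}: empty sequence")
            if len(seq) != len(qual):
                raise FastqFormatError(
                    f"record {recno}: sequence length {len(seq)} != "
                    f"quality length {len(qual)}"
                )
            bad = set(seq) - _VALID_BASES
            if bad:
                raise FastqFormatError(
                    f"record {recno}: invalid base {sorted(bad)[0]!r}"
                )
            for c in qual:
                code = ord(c)
                if not 33 <= code <= 126:
                    raise FastqFormatError(
                        f"record {recno}: quality code point {code} outside [33, 126]"
                    )
                if code > _SUSPECT_PHRED64_CODE and not allow_suspect_encoding:
                    raise FastqFormatError(
                        f"record {recno}: quality code point {code} suggests "
                        "Phred+64 input; convert to Phred+33 or override"
                    )
            yield ReadRecord(header[1:], seq, sep, qual)
    finally:
        cleanup()


def write_fastq(
    records: Iterable[ReadRecord],
    sink: str | Path | IO,
    *,
    gzip_output: bool = False,
) -> int:
    """Write records as 4-line FASTQ with LF newlines; returns the count."""
    fh, cleanup = _open_text_sink(sink, gzip_output)
    n = 0
    try:
        for rec in records:
            rec.validate()
            fh.write(f"@{rec.header}\n{rec.sequence}\n{rec.separator}\n{rec.quality}\n")
            n += 1
    finally:
        cleanup()
    return n


def read_fasta(source: str | Path | IO) -> Reference:
    """Parse FASTA (plain or gzip) into a :class:`Reference`.

    Lowercase bases are accepted and uppercased.  Any symbol outside
    {A,C,G,T,N} — including IUPAC ambiguity codes other than N — is
    rejected with an error naming the symbol and the offending record.
    """
    fh, cleanup = _open_text_source(source)
    names: list[str] = []
    seqs: list[str] = []
    try:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            if TERMINATOR in seq:
                raise FastaFormatError(
                    f"record {rec.id!r}: reserved terminator symbol "
                    f"{TERMINATOR!r} present in input"
                )
            bad = set(seq) - set(DNA + SEPARATOR)
            if bad:
                raise FastaFormatError(
                    f"record {rec.id!r}: invalid symbol {sorted(bad)[0]!r} "
                    "(IUPAC codes other than N are not supported)"
                )
            if not seq:
                raise FastaFormatError(f"record {rec.id!r}: empty sequence")
            names.append(rec.id)
            seqs.append(seq)
    finally:
        cleanup()
    if not names:
        raise FastaFormatError("no FASTA records found")
    return Reference.from_sequences(names, seqs)


def write_fasta(
    reference: Reference,
    sink: str | Path | IO,
    *,
    width: int = 60,
    gzip_output: bool = False,
) -> None:
    """Write each sequence of a Reference as a FASTA record."""
    fh, cleanup = _open_text_sink(sink, gzip_output)
    try:
        for i, name in enumerate(reference.names):
            seq = reference.sequence(i)
            fh.write(f">{name}\n")
            for j in range(0, len(seq), width):
                fh.write(seq[j : j + width] + "\n")
    finally:
        cleanup()
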