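"""FM-index over a nucleotide reference for k-mer membership queries.

The dictionary of reference k-mers is never materialised.  The reference is
stored as the Burrows-Wheeler transform (BWT) of its terminated concatenation
together with symbol-count and occurrence (rank) tables; membership of a
k-mer — exact, or within one substitution, on either strand — is answered by
backward search over those tables.  This keeps the dictionary in space linear
in the reference rather than in the number of distinct k-mers.

Symbols: the reference alphabet is {A, C, G, T, N} plus a unique terminator
that sorts before every other symbol.  ``N`` is indexed as a fifth symbol, so
an all-ACGT query can never match a reference position holding ``N``; this is
also what makes ``N`` usable as a record separator in multi-sequence
references.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import CapacityError, FormatError, IndexFormatError

TERMINATOR = "$"
SEPARATOR = "N"
DNA = "ACGT"

DEFAULT_SAMPLE_RATE = 32
DEFAULT_MAX_REFERENCE_LENGTH = 256_000_000

#: texts up to this length use a dense cumulative rank table (one int32 per
#: position per symbol); longer texts fall back to checkpointed blocks.
_DENSE_LIMIT = 4_194_304
_BLOCK = 128

_INDEX_MAGIC = b"SMQIDX01"
_INDEX_VERSION = 1

_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_RC_TABLE)[::-1]


# ---------------------------------------------------------------------------
# Reference


@dataclass
class Reference:
    """A terminated concatenation of one or more nucleotide sequences.

    Attributes
    ----------
    names:
        Identifier of each input sequence, in order.
    text:
        Uppercase concatenation over {A,C,G,T,N} with an ``N`` separator
        between records and the unique terminator appended at the end.
    boundaries:
        Start offset of each input sequence within ``text``.
    """

    names: list[str]
    text: str
    boundaries: list[int]

    @classmethod
    def from_sequences(cls, names: list[str], sequences: list[str]) -> "Reference":
        """Build a Reference by joining ``sequences`` with ``N`` separators."""
        if len(names) != len(sequences) or not names:
            raise FormatError("need one name per sequence and at least one sequence")
        parts: list[str] = []
        boundaries: list[int] = []
        offset = 0
        for i, (name, seq) in enumerate(zip(names, sequences)):
            seq = seq.upper()
            bad = set(seq) - set(DNA + SEPARATOR)
            if bad:
                raise FormatError(
                    f"record {name!r}: invalid symbol {sorted(bad)[0]!r} "
                    "(only A/C/G/T/N accepted)"
                )
            if not seq:
                raise FormatError(f"record {name!r}: empty sequence")
            if i:
                parts.append(SEPARATOR)
                offset += 1
            boundaries.append(offset)
            parts.append(seq)
            offset += len(seq)
        parts.append(TERMINATOR)
        return cls(names=list(names), text="".join(parts), boundaries=boundaries)

    def validate(self) -> None:
        if not self.text or self.text[-1] != TERMINATOR:
            raise FormatError("reference text must end with the terminator")
        if self.text.count(TERMINATOR) != 1:
            raise FormatError("terminator must occur exactly once")
        allowed = set(DNA + SEPARATOR)
        bad = set(self.text[:-1]) - allowed
        if bad:
            raise FormatError(f"invalid symbol {sorted(bad)[0]!r} in reference text")
        if len(self.names) != len(self.boundaries):
            raise FormatError("one boundary per sequence required")
        if any(b >= len(self.text) for b in self.boundaries):
            raise FormatError("boundary beyond text length")
        if any(b2 <= b1 for b1, b2 in zip(self.boundaries, self.boundaries[1:])):
            raise FormatError("boundaries must be strictly increasing")

    def sequence(self, i: int) -> str:
        """Recover the i-th input sequence (without separators/terminator)."""
        start = self.boundaries[i]
        end = (
            self.boundaries[i + 1] - 1
            if i + 1 < len(self.boundaries)
            else len(self.text) - 1
        )
        return self.text[start:end]


# ---------------------------------------------------------------------------
# Suffix array / BWT construction


def build_suffix_array(text: str) -> np.ndarray:
    """Suffix array of a terminated text by prefix doubling.

    The last character must be a unique terminator that sorts strictly
    before every other symbol in ``text``; the returned array lists suffix
    start positions in increasing lexicographic order of the suffixes.
    """
    if not text:
        raise FormatError("cannot build a suffix array of empty text")
    term = text[-1]
    if text.count(term) != 1:
        raise FormatError("terminator must be unique and final")
    if len(text) > 1 and term >= min(text[:-1]):
        raise FormatError("terminator must sort before all other symbols")
    try:
        arr = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
    except UnicodeEncodeError as exc:
        raise FormatError(f"non-ASCII symbol in text: {exc}") from exc

    n = len(arr)
    if n == 1:
        return np.zeros(1, dtype=np.int64)

    rank = np.unique(arr, return_inverse=True)[1].astype(np.int64)
    tmp = np.empty(n, dtype=np.int64)
    step = 1
    while True:
        rank2 = np.full(n, -1, dtype=np.int64)
        rank2[: n - step] = rank[step:]
        sa = np.lexsort((rank2, rank))
        tmp[sa[0]] = 0
        changed = (rank[sa[1:]] != rank[sa[:-1]]) | (rank2[sa[1:]] != rank2[sa[:-1]])
        tmp[sa[1:]] = np.cumsum(changed)
        rank, tmp = tmp.copy(), rank
        if rank[sa[-1]] == n - 1:
            return sa.astype(np.int64)
        step *= 2


def bwt_from_suffix_array(text: str, suffix_array: np.ndarray) -> str:
    """Burrows-Wheeler transform: bwt[i] = text[sa[i] - 1] (cyclically)."""
    n = len(text)
    sa = np.asarray(suffix_array, dtype=np.int64)
    if len(sa) != n:
        raise FormatError("suffix array length does not match text length")
    arr = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
    return arr[(sa - 1) % n].tobytes().decode("ascii")


def inverse_bwt(bwt: str) -> str:
    """Reconstruct the original text from its BWT by iterated LF-mapping.

    Used as the round-trip check on index construction; the terminator is
    the unique smallest character of ``bwt``.
    """
    arr = np.frombuffer(bwt.encode("ascii"), dtype=np.uint8)
    n = len(arr)
    order = np.argsort(arr, kind="stable")  # LF: row of bwt[i] in first column
    lf = np.empty(n, dtype=np.int64)
    lf[order] = np.arange(n)
    out = np.empty(n, dtype=np.uint8)
    out[n - 1] = arr.min()  # the terminator ends the text
    # Row 0 is the rotation starting with the terminator; walking LF from it
    # emits the remaining text right to left.
    row = 0
    for i in range(n - 2, -1, -1):
        out[i] = arr[row]
        row = lf[row]
    return out.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# FM-index


@dataclass(frozen=True)
class SearchResult:
    """Outcome of a k-mer membership query.

    ``concordant_positions`` holds the 0-based positions of the *query*
    k-mer that are matched without substitution in at least one occurrence
    at the minimum qualifying Hamming distance; reverse-complement hits are
    mirrored back into the original k-mer's coordinates.
    """

    found: bool
    exact: bool
    concordant_positions: frozenset[int]

    def __post_init__(self) -> None:
        if not self.found and self.concordant_positions:
            raise ValueError("unfound query cannot have concordant positions")


_EMPTY_RESULT = SearchResult(found=False, exact=False, concordant_positions=frozenset())


@dataclass
class FMIndex:
    """BWT + count/rank tables + sampled suffix array over a reference text.

    ``counts[s]`` is the number of text characters strictly smaller than
    alphabet symbol ``s``; ``occ(s, i)`` is the number of occurrences of
    symbol ``s`` in ``bwt[0:i)``.  Together they drive backward search.
    """

    bwt: np.ndarray  # uint8 ASCII codes
    counts: np.ndarray  # int64, one per alphabet symbol
    sa_samples: np.ndarray  # int64, sa[i] for i % sample_rate == 0
    sample_rate: int
    alphabet: str  # symbols in ascending ASCII order

    _sym: dict = field(init=False, repr=False, compare=False)
    _codes: np.ndarray = field(init=False, repr=False, compare=False)
    _dense: np.ndarray | None = field(init=False, repr=False, compare=False)
    _ck: np.ndarray | None = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._sym = {c: i for i, c in enumerate(self.alphabet)}
        self._codes = np.frombuffer(self.alphabet.encode("ascii"), dtype=np.uint8)
        n = len(self.bwt)
        nsym = len(self.alphabet)
        if n <= _DENSE_LIMIT:
            dense = np.zeros((n + 1, nsym), dtype=np.int32)
            for s in range(nsym):
                dense[1:, s] = np.cumsum(self.bwt == self._codes[s])
            self._dense = dense
            self._ck = None
        else:
            nblk = n // _BLOCK + 1
            ck = np.zeros((nblk + 1, nsym), dtype=np.int64)
            ends = np.minimum(np.arange(1, nblk + 1) * _BLOCK, n)
            for s in range(nsym):
                csum = np.cumsum(self.bwt == self._codes[s])
                ck[1:, s] = csum[ends - 1]
            self._dense = None
            self._ck = ck

    @property
    def n(self) -> int:
        return len(self.bwt)

    def occ(self, sym_index: int, i: int) -> int:
        """Occurrences of alphabet symbol ``sym_index`` in ``bwt[0:i)``."""
        if self._dense is not None:
            return int(self._dense[i, sym_index])
        blk, rem = divmod(i, _BLOCK)
        c = int(self._ck[blk, sym_index])
        if rem:
            c += int(
                np.count_nonzero(
                    self.bwt[blk * _BLOCK : i] == self._codes[sym_index]
                )
            )
        return c

    def extend(self, lo: int, hi: int, ch: str) -> tuple[int, int] | None:
        """Prepend ``ch`` to the pattern of suffix-array interval [lo, hi).

        Returns the narrowed interval, or None if ``ch`` is not an indexed
        symbol or the interval becomes empty.
        """
        s = self._sym.get(ch)
        if s is None:
            return None
        base = int(self.counts[s])
        lo2 = base + self.occ(s, lo)
        hi2 = base + self.occ(s, hi)
        if lo2 >= hi2:
            return None
        return lo2, hi2


def build_index(
    reference: Reference,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    max_length: int = DEFAULT_MAX_REFERENCE_LENGTH,
) -> FMIndex:
    """Build the FM-index of a validated reference.

    ``max_length`` is a desk-scale capacity guard on the in-memory suffix
    array build; exceeding it raises :class:`CapacityError`.
    """
    reference.validate()
    if sample_rate < 1:
        raise ValueError("sample_rate must be a positive integer")
    if len(reference.text) > max_length:
        raise CapacityError(
            f"reference of {len(reference.text)} characters exceeds the "
            f"configured in-memory build capacity of {max_length}"
        )
    sa = build_suffix_array(reference.text)
    bwt = bwt_from_suffix_array(reference.text, sa)
    arr = np.frombuffer(bwt.encode("ascii"), dtype=np.uint8)
    alphabet = "".join(sorted(set(bwt)))
    totals = np.array([np.count_nonzero(arr == ord(c)) for c in alphabet], dtype=np.int64)
    counts = np.concatenate(([0], np.cumsum(totals)[:-1]))
    return FMIndex(
        bwt=arr,
        counts=counts,
        sa_samples=sa[::sample_rate].copy(),
        sample_rate=sample_rate,
        alphabet=alphabet,
    )


def backward_search_exact(index: FMIndex, pattern: str) -> int:
    """Number of exact occurrences of ``pattern`` in the indexed text.

    The pattern must be non-empty; any symbol outside {A,C,G,T} yields a
    count of 0 by contract (queries never match the indexed ``N`` or the
    terminator).
    """
    if not pattern:
        raise ValueError("empty pattern rejected")
    if any(c not in DNA for c in pattern):
        return 0
    lo, hi = 0, index.n
    for ch in reversed(pattern):
        iv = index.extend(lo, hi, ch)
        if iv is None:
            return 0
        lo, hi = iv
    return hi - lo


def _suffix_intervals(index: FMIndex, pat: str) -> list[tuple[int, int] | None]:
    """Intervals of every suffix pat[t:]; None once the interval is empty."""
    k = len(pat)
    iv: list[tuple[int, int] | None] = [None] * (k + 1)
    lo, hi = 0, index.n
    iv[k] = (lo, hi)
    for t in range(k - 1, -1, -1):
        nxt = index.extend(lo, hi, pat[t])
        if nxt is None:
            break
        lo, hi = nxt
        iv[t] = (lo, hi)
    return iv


def _one_mismatch_positions(
    index: FMIndex, pat: str, iv: list[tuple[int, int] | None]
) -> set[int]:
    """Pattern positions j admitting an occurrence with a substitution at j.

    For each j whose exact suffix pat[j+1:] is present, try the three
    substitute bases and extend exactly leftwards; early exit on empty
    intervals keeps this cheap on random misses.
    """
    hits: set[int] = set()
    k = len(pat)
    for j in range(k - 1, -1, -1):
        base = iv[j + 1]
        if base is None:
            continue
        for b in DNA:
            if b == pat[j]:
                continue
            cur = index.extend(base[0], base[1], b)
            if cur is None:
                continue
            ok = True
            for t in range(j - 1, -1, -1):
                cur = index.extend(cur[0], cur[1], pat[t])
                if cur is None:
                    ok = False
                    break
            if ok:
                hits.add(j)
    return hits


def search_membership(
    index: FMIndex,
    kmer: str,
    max_mismatches: int = 1,
    both_strands: bool = True,
) -> SearchResult:
    """Is ``kmer`` in the reference dictionary, within ``max_mismatches``?

    With ``both_strands`` the reverse complement is also queried and any
    mismatch position is mirrored back into the original k-mer's
    coordinates.  A k-mer containing a symbol outside {A,C,G,T} is never
    found (contract, not an exception).
    """
    k = len(kmer)
    if k < 2:
        raise ValueError("k-mer length must be at least 2")
    if max_mismatches not in (0, 1):
        raise ValueError("max_mismatches must be 0 or 1")
    if any(c not in DNA for c in kmer):
        return _EMPTY_RESULT

    patterns = [kmer]
    if both_strands:
        patterns.append(reverse_complement(kmer))

    suffix_tables = [_suffix_intervals(index, p) for p in patterns]
    if any(iv[0] is not None for iv in suffix_tables):
        return SearchResult(True, True, frozenset(range(k)))
    if max_mismatches == 0:
        return _EMPTY_RESULT

    mismatch_at: set[int] = set()
    for strand, (pat, iv) in enumerate(zip(patterns, suffix_tables)):
        for j in _one_mismatch_positions(index, pat, iv):
            mismatch_at.add(j if strand == 0 else k - 1 - j)
    if not mismatch_at:
        return _EMPTY_RESULT
    # Each 1-mismatch occurrence is concordant everywhere except its own
    # substituted position; the union over occurrences excludes a position
    # only when every occurrence substitutes that same position.
    if len(mismatch_at) == 1:
        concordant = frozenset(range(k)) - mismatch_at
    else:
        concordant = frozenset(range(k))
    return SearchResult(True, False, concordant)


# ---------------------------------------------------------------------------
# Serialization
#
# Byte layout (all little-endian), designed so two builds of the same
# reference are byte-identical:
#   magic            8 bytes  b"SMQIDX01"
#   version          u32
#   alphabet_len     u8, then alphabet bytes (ASCII, ascending)
#   sample_rate      u32
#   n                u64      length of bwt
#   n_samples        u64      number of suffix-array samples
#   bwt              n bytes
#   counts           alphabet_len * i64
#   sa_samples       n_samples * i64
#   crc32            u32      of all preceding bytes


def save_index(index: FMIndex, path: str | Path) -> None:
    """Serialize the index to a single binary file (documented layout)."""
    parts = [
        _INDEX_MAGIC,
        struct.pack("<I", _INDEX_VERSION),
        struct.pack("<B", len(index.alphabet)),
        index.alphabet.encode("ascii"),
        struct.pack("<I", index.sample_rate),
        struct.pack("<Q", len(index.bwt)),
        struct.pack("<Q", len(index.sa_samples)),
        index.bwt.astype(np.uint8).tobytes(),
        index.counts.astype("<i8").tobytes(),
        index.sa_samples.astype("<i8").tobytes(),
    ]
    payload = b"".join(parts)
    payload += struct.pack("<I", zlib.crc32(payload) & 0xFFFFFFFF)
    Path(path).write_bytes(payload)


def load_index(path: str | Path) -> FMIndex:
    """Load an index written by :func:`save_index`.

    Any truncation, bad magic, version mismatch or checksum failure raises
    :class:`IndexFormatError`; the file is never silently misread.
    """
    try:
        data = Path(path).read_bytes()
    except OSError as exc:
        raise IndexFormatError(f"cannot read index file {path}: {exc}") from exc

    def fail(msg: str) -> "IndexFormatError":
        return IndexFormatError(f"index file {path}: {msg}")

    if len(data) < 8 or data[:8] != _INDEX_MAGIC:
        raise fail("bad magic bytes (not an index file)")
    if len(data) < 4:
        raise fail("truncated header")
    pos = 8
    try:
        (version,) = struct.unpack_from("<I", data, pos)
        pos += 4
        if version != _INDEX_VERSION:
            raise fail(f"unsupported format version {version}")
        (alen,) = struct.unpack_from("<B", data, pos)
        pos += 1
        alphabet = data[pos : pos + alen].decode("ascii")
        if len(alphabet) != alen:
            raise fail("truncated alphabet")
        pos += alen
        sample_rate, = struct.unpack_from("<I", data, pos)
        pos += 4
        n, n_samples = struct.unpack_from("<QQ", data, pos)
        pos += 16
        need = pos + n + alen * 8 + n_samples * 8 + 4
        if len(data) != need:
            raise fail(f"size mismatch (expected {need} bytes, found {len(data)})")
        (crc,) = struct.unpack_from("<I", data, len(data) - 4)
        if crc != (zlib.crc32(data[:-4]) & 0xFFFFFFFF):
            raise fail("checksum failure (corrupted file)")
        bwt = np.frombuffer(data, dtype=np.uint8, count=n, offset=pos).copy()
        pos += n
        counts = np.frombuffer(data, dtype="<i8", count=alen, offset=pos).astype(np.int64)
        pos += alen * 8
        sa_samples = np.frombuffer(data, dtype="<i8", count=n_samples, offset=pos).astype(
            np.int64
        )
    except struct.error as exc:
        raise fail(f"truncated file: {exc}") from exc
    return FMIndex(
        bwt=bwt,
        counts=counts,
        sa_samples=sa_samples,
        sample_rate=sample_rate,
        alphabet=alphabet,
    )
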