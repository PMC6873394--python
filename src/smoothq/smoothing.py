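"""Per-base lossy smoothing of FASTQ quality scores.

A read is decomposed into its overlapping k-mers; each k-mer is looked up
in the reference dictionary (the FM-index), and a base whose every covering
k-mer is found and concordant at that base has its quality replaced with a
constant high-confidence value.  One discordant covering k-mer is enough to
leave the quality untouched.  Two Phred thresholds modulate the rule:

* lower threshold (L.T.): a quality strictly below it is never modified,
  and its base disqualifies every covering k-mer from being queried — low
  quality read tails are therefore left alone (trimming behaviour);
* higher threshold (H.T.): a quality strictly above it is replaced without
  consulting the dictionary at all (fast path).

Rule precedence per base is fixed and test-pinned: (1) fast path,
(2) low-quality keep, (3) uncovered keep, (4) concordance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .fastq_io import PHRED_OFFSET, ReadRecord
from .fmindex import DNA, FMIndex, SearchResult, search_membership

MAX_PHRED = 93  # '~' in Phred+33

# Per-base outcome labels (which rule fired).
FASTPATH = "fastpath"
KEPT_LOW = "kept_low"
KEPT_UNCOVERED = "kept_uncovered"
KEPT_DISCORDANT = "kept_discordant"
SMOOTHED = "smoothed"

_ACGT_CODES = np.frombuffer(DNA.encode("ascii"), dtype=np.uint8)

#: bound on the k-mer result cache carried across reads of a stream
_CACHE_LIMIT = 1 << 20


@dataclass
class SmoothingParams:
    """Tunable parameters of the smoothing rule.

    Defaults: k=32, one mismatch allowed, L.T.=6, H.T.=40, replacement
    quality Phred 40 ('I'), Phred+33 encoding.
    """

    k: int = 32
    max_mismatches: int = 1
    lower_threshold: int = 6
    higher_threshold: int = 40
    replacement_quality: int = 40
    offset: int = PHRED_OFFSET

    def validate(self) -> None:
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if self.max_mismatches not in (0, 1):
            raise ValueError("max_mismatches must be 0 or 1")
        if not 0 <= self.lower_threshold <= self.higher_threshold <= MAX_PHRED:
            raise ValueError(
                "thresholds must satisfy 0 <= lower <= higher <= 93"
            )
        if not 0 <= self.replacement_quality <= MAX_PHRED:
            raise ValueError("replacement_quality must be in [0, 93]")

    @property
    def replacement_char(self) -> str:
        return chr(self.replacement_quality + self.offset)


@dataclass
class SmoothingReport:
    """Per-run counters; the five base counters partition all bases."""

    reads_processed: int = 0
    bases_smoothed: int = 0
    bases_kept_low_quality: int = 0
    bases_kept_discordant: int = 0
    bases_kept_uncovered: int = 0
    bases_fastpathed: int = 0
    kmers_queried: int = 0
    kmers_skipped: int = 0
    kmers_found: int = 0

    @property
    def bases_total(self) -> int:
        return (
            self.bases_smoothed
            + self.bases_kept_low_quality
            + self.bases_kept_discordant
            + self.bases_kept_uncovered
            + self.bases_fastpathed
        )

    def as_tsv(self) -> str:
        fields = [
            ("reads_processed", self.reads_processed),
            ("bases_total", self.bases_total),
            ("bases_smoothed", self.bases_smoothed),
            ("bases_kept_low_quality", self.bases_kept_low_quality),
            ("bases_kept_discordant", self.bases_kept_discordant),
            ("bases_kept_uncovered", self.bases_kept_uncovered),
            ("bases_fastpathed", self.bases_fastpathed),
            ("kmers_queried", self.kmers_queried),
            ("kmers_skipped", self.kmers_skipped),
            ("kmers_found", self.kmers_found),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in fields)

    def as_dict(self) -> dict:
        return {
            "reads_processed": self.reads_processed,
            "bases_total": self.bases_total,
            "bases_smoothed": self.bases_smoothed,
            "bases_kept_low_quality": self.bases_kept_low_quality,
            "bases_kept_discordant": self.bases_kept_discordant,
            "bases_kept_uncovered": self.bases_kept_uncovered,
            "bases_fastpathed": self.bases_fastpathed,
            "kmers_queried": self.kmers_queried,
            "kmers_skipped": self.kmers_skipped,
            "kmers_found": self.kmers_found,
        }


def phred_error_probability(q: int) -> float:
    """Base-call error probability of Phred score q: 10**(-q/10)."""
    if not 0 <= q <= MAX_PHRED:
        raise ValueError(f"Phred score {q} outside [0, {MAX_PHRED}]")
    return 10.0 ** (-q / 10.0)


def queried_kmer_mask(read: ReadRecord, params: SmoothingParams) -> np.ndarray:
    """Boolean flag per k-mer start: is this window eligible for querying?

    A window is queried iff every position in it has quality >= L.T. and an
    A/C/G/T base.  Reads shorter than k yield an empty mask.
    """
    params.validate()
    n = len(read.sequence)
    k = params.k
    if n < k:
        return np.zeros(0, dtype=bool)
    seq = np.frombuffer(read.sequence.upper().encode("ascii"), dtype=np.uint8)
    q = np.frombuffer(read.quality.encode("ascii"), dtype=np.uint8).astype(np.int32)
    q -= params.offset
    ok = (q >= params.lower_threshold) & np.isin(seq, _ACGT_CODES)
    cbad = np.concatenate(([0], np.cumsum(~ok)))
    return (cbad[k:] - cbad[: n - k + 1]) == 0


def _lookup(
    index: FMIndex,
    kmer: str,
    params: SmoothingParams,
    cache: dict[str, SearchResult] | None,
) -> SearchResult:
    if cache is not None:
        hit = cache.get(kmer)
        if hit is not None:
            return hit
    res = search_membership(index, kmer, params.max_mismatches, both_strands=True)
    if cache is not None:
        if len(cache) >= _CACHE_LIMIT:
            cache.clear()
        cache[kmer] = res
    return res


def smooth_read(
    read: ReadRecord,
    index: FMIndex,
    params: SmoothingParams,
    *,
    cache: dict[str, SearchResult] | None = None,
    report: SmoothingReport | None = None,
) -> tuple[ReadRecord, list[str]]:
    """Apply the per-base smoothing rule to one read.

    Returns a new record (sequence, header and separator unchanged) and the
    per-base outcome labels.  ``cache`` memoises k-mer lookups across calls;
    ``report`` accumulates counters when provided.
    """
    params.validate()
    read.validate()
    n = len(read.sequence)
    k = params.k
    q = np.frombuffer(read.quality.encode("ascii"), dtype=np.uint8).astype(np.int32)
    q -= params.offset

    fast = q > params.higher_threshold
    low = ~fast & (q < params.lower_threshold)
    undecided = ~fast & ~low

    mask = queried_kmer_mask(read, params)
    starts = np.flatnonzero(mask)
    cov = np.zeros(n + 1, dtype=np.int64)
    if len(starts):
        np.add.at(cov, starts, 1)
        np.add.at(cov, starts + k, -1)
    covered = np.cumsum(cov[:n]) > 0

    if report is not None:
        report.reads_processed += 1
        report.kmers_skipped += max(n - k + 1, 0) - len(starts)

    out_q = np.where(fast, params.replacement_quality, q)
    labels = [""] * n
    for p in np.flatnonzero(fast):
        labels[p] = FASTPATH
    for p in np.flatnonzero(low):
        labels[p] = KEPT_LOW

    # Only windows covering at least one undecided base need a dictionary
    # lookup; the rest of the eligible windows would decide nothing.
    need = undecided & covered
    results: dict[int, SearchResult] = {}
    if need.any():
        cneed = np.concatenate(([0], np.cumsum(need)))
        seq_u = read.sequence.upper()
        for i in starts:
            if cneed[i + k] - cneed[i] == 0:
                continue
            res = _lookup(index, seq_u[i : i + k], params, cache)
            results[int(i)] = res
            if report is not None:
                report.kmers_queried += 1
                if res.found:
                    report.kmers_found += 1

    mask_list = mask.tolist()
    last_start = n - k
    for p in np.flatnonzero(undecided):
        p = int(p)
        if not covered[p]:
            labels[p] = KEPT_UNCOVERED
            continue
        concordant = True
        for i in range(max(0, p - k + 1), min(p, last_start) + 1):
            if not mask_list[i]:
                continue
            res = results[i]
            if not res.found or (p - i) not in res.concordant_positions:
                concordant = False
                break
        if concordant:
            out_q[p] = params.replacement_quality
            labels[p] = SMOOTHED
        else:
            labels[p] = KEPT_DISCORDANT

    if report is not None:
        report.bases_fastpathed += int(fast.sum())
        report.bases_kept_low_quality += int(low.sum())
        report.bases_kept_uncovered += labels.count(KEPT_UNCOVERED)
        report.bases_kept_discordant += labels.count(KEPT_DISCORDANT)
        report.bases_smoothed += labels.count(SMOOTHED)

    quality = (out_q + params.offset).astype(np.uint8).tobytes().decode("ascii")
    new_rec = ReadRecord(read.header, read.sequence, read.separator, quality)
    return new_rec, labels


def smooth_stream(
    records: Iterable[ReadRecord],
    index: FMIndex,
    params: SmoothingParams | None = None,
) -> tuple[Iterator[ReadRecord], SmoothingReport]:
    """Smooth a stream of records, preserving order, one record at a time.

    Returns a lazy iterator over smoothed records plus the report object,
    whose counters are final once the iterator is exhausted.  Each read is
    processed independently; a shared k-mer cache only memoises identical
    lookups.
    """
    if params is None:
        params = SmoothingParams()
    params.validate()
    report = SmoothingReport()
    cache: dict[str, SearchResult] = {}

    def gen() -> Iterator[ReadRecord]:
        for rec in records:
            out, _ = smooth_read(rec, index, params, cache=cache, report=report)
            yield out

    return gen(), report
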