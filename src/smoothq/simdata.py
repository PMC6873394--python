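"""Synthetic references and Illumina-like reads with known error positions.

The generator emulates a single-end Illumina-like substitution-error
process: reads are drawn uniformly from either strand of a uniform random
reference, each base is substituted independently with a fixed error rate,
and Phred qualities are sampled from two distributions — one for correct
bases (high scores) and one for erroneous bases (low scores), reflecting
the tendency of base callers to assign low confidence to miscalls.  Error
positions are recorded exactly, so downstream behaviour at true errors can
be asserted rather than estimated.

No indels, no quality-by-cycle structure, no paired-end insert model: the
smoothing rule is Hamming-based, so substitutions are the error class that
exercises it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .fastq_io import PHRED_OFFSET, ReadRecord
from .fmindex import DNA, Reference, reverse_complement

_BASES = np.frombuffer(DNA.encode("ascii"), dtype=np.uint8)


def uniform_quality_distribution(lo: int, hi: int) -> np.ndarray:
    """Uniform distribution over Phred scores lo..hi (inclusive), as a
    probability vector over 0..93."""
    if not 0 <= lo <= hi <= 93:
        raise ValueError("quality range must satisfy 0 <= lo <= hi <= 93")
    p = np.zeros(94)
    p[lo : hi + 1] = 1.0 / (hi - lo + 1)
    return p


def _default_correct() -> np.ndarray:
    return uniform_quality_distribution(30, 41)


def _default_error() -> np.ndarray:
    return uniform_quality_distribution(2, 20)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated read set.

    Default quality model: correct bases uniform Phred 30-41 (typical
    modern Illumina range), erroneous bases uniform Phred 2-20 — chosen to
    exercise both the trimming and the fast-path thresholds.
    """

    reference_length: int = 100_000
    n_reads: int = 1_000
    read_length: int = 100
    error_rate: float = 0.01
    quality_correct: np.ndarray = field(default_factory=_default_correct)
    quality_error: np.ndarray = field(default_factory=_default_error)
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if self.read_length > self.reference_length:
            raise ValueError("read_length cannot exceed reference_length")
        if self.read_length < 1 or self.n_reads < 0:
            raise ValueError("read_length >= 1 and n_reads >= 0 required")
        for name, dist in (
            ("quality_correct", self.quality_correct),
            ("quality_error", self.quality_error),
        ):
            d = np.asarray(dist, dtype=float)
            if d.shape != (94,) or d.min() < 0 or abs(d.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a probability vector over 0..93")


@dataclass
class SimulatedRead:
    """A read plus its ground truth: origin and true error positions."""

    record: ReadRecord
    origin: int
    strand: str  # '+' or '-'
    error_positions: frozenset[int]


def generate_reference(
    length: int, seed: int, name: str = "chrSim"
) -> Reference:
    """Uniform i.i.d. ACGT reference of the given length (deterministic in
    the seed)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    seq = _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
    return Reference.from_sequences([name], [seq])


def simulate_reads(
    reference: Reference, config: SimulationConfig
) -> list[SimulatedRead]:
    """Draw reads per the configured error and quality model.

    Origins are uniform over valid offsets of the concatenated reference
    (windows containing N, e.g. record separators, are redrawn); strands
    are uniform; substitutions are i.i.d. at ``error_rate`` to a uniformly
    chosen different base.
    """
    config.validate()
    reference.validate()
    text = reference.text[:-1]  # drop terminator
    L = config.read_length
    if L > len(text):
        raise ValueError("read_length exceeds reference length")
    rng = np.random.default_rng(config.seed)
    qc = np.asarray(config.quality_correct, dtype=float)
    qe = np.asarray(config.quality_error, dtype=float)

    reads: list[SimulatedRead] = []
    n_offsets = len(text) - L + 1
    for i in range(config.n_reads):
        while True:
            off = int(rng.integers(0, n_offsets))
            template = text[off : off + L]
            if "N" not in template:
                break
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        if strand == "-":
            template = reverse_complement(template)
        seq = np.frombuffer(template.encode("ascii"), dtype=np.uint8).copy()
        err = rng.random(L) < config.error_rate
        err_idx = np.flatnonzero(err)
        for p in err_idx:
            choices = _BASES[_BASES != seq[p]]
            seq[p] = choices[rng.integers(0, 3)]
        quals = rng.choice(94, size=L, p=qc)
        if len(err_idx):
            quals[err_idx] = rng.choice(94, size=len(err_idx), p=qe)
        record = ReadRecord(
            header=f"sim_{i:06d}",
            sequence=seq.tobytes().decode("ascii"),
            separator="+",
            quality=(quals + PHRED_OFFSET).astype(np.uint8).tobytes().decode("ascii"),
        )
        reads.append(
            SimulatedRead(
                record=record,
                origin=off,
                strand=strand,
                error_positions=frozenset(int(p) for p in err_idx),
            )
        )
    return reads


def write_truth(reads: Sequence[SimulatedRead], path: str | Path) -> None:
    """Tab-separated ground truth: read id, origin offset, strand,
    comma-separated error positions (empty field if none)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for r in reads:
            w.writerow(
                [
                    r.record.header,
                    r.origin,
                    r.strand,
                    ",".join(str(p) for p in sorted(r.error_positions)),
                ]
            )


def read_truth(path: str | Path) -> list[tuple[str, int, str, frozenset[int]]]:
    """Parse a truth file written by :func:`write_truth`."""
    rows = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row:
                continue
            rid, off, strand, errs = row
            positions = frozenset(int(p) for p in errs.split(",") if p != "")
            rows.append((rid, int(off), strand, positions))
    return rows
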