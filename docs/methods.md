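# Methods

## The smoothing model

`smoothq` treats a reference genome as a dictionary of trusted k-mers and
asks, for every base of every read, whether the sequence context around that
base is concordant with the dictionary. The underlying assumption is the
usual alignment-free one: if a k-mer (or its reverse complement) occurs in
the reference within a small Hamming distance, the bases it matches exactly
are very likely correct calls, so their individual quality scores carry
little information beyond "high confidence" and can be replaced by a
constant. Bases that disagree — sequencing errors or true variants — are
exactly the ones whose original quality must survive, so one discordant
covering k-mer is enough to protect a base. This is deliberately
conservative: a base is smoothed only when *every* queried k-mer covering it
is found and concordant there, not when merely one is.

The per-base decision is a fixed precedence of four rules (fast path,
low-quality keep, uncovered keep, concordance), evaluated in that order.
The ordering is not arbitrary only in one respect — the two threshold rules
must precede the dictionary rules so that lookups can be skipped — and the
tests pin it so the output is a deterministic function of
(read, reference, parameters). Threshold comparisons are strict on both
sides: a quality strictly above H.T. takes the fast path, a quality strictly
below L.T. is untouchable. Since L.T. ≤ H.T. is enforced, no base can
satisfy both.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 32 | k-mer length. Long enough that the 4^k space dwarfs any genome, so chance collisions between unrelated k-mers are rare; short enough that a read-length window usually contains an error-free k-mer. |
| `max_mismatches` | 1 | Hamming budget of the dictionary lookup. With 1, a k-mer containing a single substitution still counts as found, but the substituted position itself is non-concordant and keeps its quality. |
| `lower_threshold` (L.T.) | 6 (Phred) | Qualities below it are never modified, and their bases disqualify every covering k-mer from being queried. Phred 6 is the character `'` and corresponds to an error probability of 10^(−0.6) ≈ 0.25119 — a base this unreliable would poison every window containing it. Acts as a trimming mechanism on low-quality tails. |
| `higher_threshold` (H.T.) | 40 (Phred) | Qualities above it are replaced without any lookup. Purely a speed lever: raising it toward 93 disables the fast path entirely. |
| `replacement_quality` | 40 (Phred, `I`) | The constant written at smoothed and fast-pathed positions; top of the Illumina 0–41 range, i.e. "almost certainly correct". |
| `offset` | 33 | Phred+33 encoding. Phred+64 input is detected heuristically (any code point > 104) and rejected unless overridden. |

## The index

The dictionary is an FM-index of the reference concatenation: suffix array →
BWT → per-symbol counts plus an occurrence (rank) structure. Membership of a
k-mer is answered by backward search in O(k) rank queries; the one-mismatch
search first computes the suffix-array intervals of every exact suffix of
the pattern, then branches once per position and substitute base, extending
exactly leftwards. On random misses the suffix intervals empty out within
~log₄(reference length) symbols, so the branch-and-extend stays cheap.

Construction uses prefix doubling over numpy argsorts (O(n log n)); at the
desk scale this package targets (a capacity guard rejects references above
256 Mbp) a 100 kb reference indexes in well under a second and a few Mbp in
seconds. The rank structure is adaptive: a dense cumulative table (one int32
per position per symbol) up to 4 Mbp for fast queries, checkpointed blocks
of 128 positions above that to keep memory linear with a small constant.

Multi-record FASTA references are joined with a single `N` between records.
`N` is indexed as a fifth symbol and query k-mers are pure A/C/G/T (the
substitution branch only tries A/C/G/T), so no query can ever match across a
record boundary or against an ambiguous reference position — deterministic,
unlike the common trick of randomising N into a base. Queries are made
against the forward concatenation and, by default, also as the reverse
complement of the k-mer (`both_strands=True`), which is the standard
read-versus-reference semantics; a reverse-complement hit has its mismatch
position mirrored back into read coordinates.

The serialized index is a single little-endian binary with magic bytes,
version, alphabet, sampling rate, the raw arrays and a CRC32 trailer; rank
tables are rebuilt on load, so two builds of the same reference are
byte-identical. Suffix-array samples (every 32nd entry) are retained for
debugging only — smoothing needs membership, never positions.

## The synthetic data generator

`simdata` emulates a single-end Illumina-like substitution error process:
a uniform i.i.d. ACGT reference; read origins uniform over offsets and
strands; i.i.d. substitutions at a configurable rate to a uniformly chosen
different base; qualities drawn from one distribution at correct positions
(default uniform Phred 30–41) and another at error positions (default
uniform Phred 2–20, reflecting base callers' tendency to score miscalls
low). Defaults were chosen to straddle both thresholds so that trimming,
fast path and concordance rules are all exercised. Every read records its
true origin and error positions, so tests assert behaviour at known errors
rather than estimating it.

What the generator does *not* model — indels, quality-by-cycle decay, GC
bias, PCR duplicates, paired-end inserts, repeat structure of real
genomes — bounds what passing tests show: they validate the algorithm's
contracts (concordant bases smoothed, suspect bases untouched, order and
sequence bytes preserved), not genotyping accuracy on human data. Real
genomes are highly repetitive, so real k-mer hit rates, and hence achieved
compression, will differ from the uniform-reference figures. Indels in
particular are invisible to a Hamming-based rule; a read spanning an indel
simply has all its covering k-mers miss, leaving those qualities untouched
(fail-safe, not wrong).

## Evaluation metrics

The compression ratio is uncompressed size / compressed size of the whole
FASTQ byte stream, measured with the standard library's gzip, bzip2 and LZMA
codecs at their default levels (the level is recorded in the summary).
Order-0 Shannon entropy of the concatenated quality stream is reported as a
diagnostic; it upper-bounds what an order-0 entropy coder could do and drops
to 0 when every quality becomes the replacement character. Entropy reduction
does not *guarantee* a smaller file for an arbitrary compressor (DEFLATE
also models the sequence lines), so the direction claim is asserted on the
standard benchmark configuration, not universally.

`smoothing_fidelity` joins the simulator's truth file against the original
and smoothed FASTQ and counts error-position qualities kept versus raised —
a desk-scale proxy for the downstream question of whether smoothing hides
real disagreements.

## Numerical and edge-case choices

- Reads shorter than k, and bases whose every covering k-mer was
  disqualified, are kept unchanged (rule 3).
- A k-mer containing `N` in the read is never queried; the N base itself
  falls through to rules 2/3.
- When a k-mer is found only at Hamming distance 1, the concordant set is
  the union over all distance-1 occurrences of their exactly-matched
  positions: a position is excluded only if *every* such occurrence
  substitutes it, which with the up-to-one-mismatch budget means exclusion
  happens exactly when a single position accounts for all hits.
- The whole-read fast path (every base above H.T.) is an optimization with
  output identical to per-base application; the implementation simply
  issues no lookups for windows that cover no undecided base.
- The k-mer lookup cache is an exact memo keyed by k-mer string, bounded at
  2^20 entries and cleared when full; it changes throughput, never results.
- Suffix-array construction requires a unique terminator sorting before all
  symbols; empty patterns are rejected rather than defined to match
  everywhere.

## Problem sizes

The standard benchmark configuration used by the test suite and the
acceptance script is a 100 kb reference with 1 000 reads of 100 bp
(1× coverage) — large enough that chance 32-mer collisions against an
unrelated reference are practically impossible (expected ≈ 10⁵·10⁵/4³² ≈
5·10⁻¹⁰ per strand pair) and that binomial checks on error counts have
power, small enough to run comfortably on one core. Randomized equivalence
sweeps against the brute-force oracles use references ≤ 200 bp with k ≤ 8
so that neighbor enumeration and literal rule application stay exact and
fast.

## Known limitations

- Capacity: the in-memory suffix-array build is desk-scale; whole mammalian
  genomes are out of scope by design (the capacity guard), although the
  index format and query path would support them.
- Pure-Python query loop: throughput is thousands of reads per second, not
  millions; the contracts (streaming, order preservation, pipe safety) are
  the point, not wall-clock parity with C implementations.
- Only substitution concordance: gapped matches are not searched.
- Single quality encoding (Phred+33); no conversion is performed.
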