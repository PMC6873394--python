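# smoothq

Reference-based lossy smoothing of FASTQ quality scores.

Most of the entropy in a FASTQ file lives in its quality string: the four
nucleotides compress to ~2 bits each, but Phred qualities span dozens of
symbols and resist general-purpose compressors. Yet much of that diversity is
noise — when the sequence context around a base agrees with a trusted
reference genome, a detailed per-base confidence adds little over "this base
is almost certainly correct". `smoothq` exploits this: it replaces the quality
of every *concordant* base with a single high-confidence value and leaves
every *suspect* base untouched, so the quality stream collapses toward a
constant and the file compresses far better, while disagreements with the
reference (candidate variants, sequencing errors) keep their original scores.

It is aimed at people who store or move large read sets — sequencing cores,
archives, anyone shipping FASTQ between machines — and who want better
compression without discarding the quality signal where it matters.

## Method

A read of length *n* is decomposed into its *n − k + 1* overlapping k-mers
(default *k* = 32). Each eligible k-mer is looked up in a dictionary of
reference k-mers; a base is **concordant** when every queried k-mer covering
it is found in the dictionary and matches the reference at that base. For a
base at position *p* with Phred score *q(p)*, the first matching rule applies:

1. **fast path** — if *q(p)* > H.T. (default 40), replace with the
   replacement score (no lookup needed);
2. **low-quality keep** — if *q(p)* < L.T. (default 6, the character `'`,
   error probability 10^(−6/10) ≈ 0.25119), keep the original score.
   A base below L.T. also disqualifies every k-mer covering it from being
   queried, which trims low-quality read tails;
3. **uncovered keep** — if no queried k-mer covers *p*, keep;
4. **concordance** — if all queried covering k-mers are found (up to one
   substitution, either strand) and *p* is matched without substitution in
   each, replace with the replacement score (default Phred 40, `I`);
   otherwise keep. One discordant k-mer is enough to protect a base.

The dictionary is never materialised as a k-mer list. The reference is stored
as an FM-index — the Burrows–Wheeler transform of the terminated reference
plus symbol-count and rank tables — and each k-mer is resolved by backward
search in *O(k)* rank queries (a bounded-substitution variant handles the
one-mismatch case). Space is linear in the reference, not in the number of
distinct k-mers.

## Worked example

```sh
# simulate a 100 kb reference and 1 000 error-free 100 bp reads
smoothq simulate --seed 1 --ref-length 100000 --n-reads 1000 \
    --read-length 100 --error-rate 0.0 -o sim

# build the FM-index of the reference
smoothq index sim.ref.fasta -o sim.idx

# smooth the reads (stdout carries FASTQ only; the report goes to stderr)
smoothq smooth -x sim.idx -i sim.reads.fastq -o smoothed.fastq

# measure the effect
smoothq eval sim.reads.fastq --compressor gzip | grep -E 'ratio|entropy'
smoothq eval smoothed.fastq  --compressor gzip | grep -E 'ratio|entropy'
```

The smoothing report printed on stderr for this run:

```
reads_processed	1000
bases_total	100000
bases_smoothed	91654
bases_kept_low_quality	0
bases_kept_discordant	0
bases_kept_uncovered	0
bases_fastpathed	8346
kmers_queried	69000
kmers_skipped	0
kmers_found	69000
```

Every queried k-mer was found (the reads are error-free), so no base was kept
as discordant: the simulator draws correct-base qualities in 30–41, so the
8 346 bases scoring 41 (> H.T.) took the fast path and every other base was
smoothed by concordance. Either way each quality became the replacement
character `I`, and the `eval` lines show the effect:

```
ratio	2.2566          # original
quality_entropy_bits	3.5849
ratio	6.1133          # smoothed
quality_entropy_bits	0.0000
```

`smooth` composes with pipes and gzip on both ends
(`zcat in.fastq.gz | smoothq smooth -x ref.idx | gzip > out.fastq.gz`), and
output record order always matches input order, so paired files processed
independently stay paired.

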