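"""Brute-force oracles, independent of the indexed implementations.

Everything here works by naive comparison, substring scanning or literal
rule application so that the FM-index backward search and the per-base
smoothing rule can be checked against an implementation too slow to use
but too simple to be wrong.
"""

from __future__ import annotations

from smoothq import ReadRecord, SearchResult, reverse_complement
from smoothq.smoothing import SmoothingParams

DNA = "ACGT"


def naive_suffix_array(text: str) -> list[int]:
    return sorted(range(len(text)), key=lambda i: text[i:])


def naive_count(text: str, pattern: str) -> int:
    """Overlapping occurrence count by scanning."""
    return sum(text.startswith(pattern, i) for i in range(len(text)))


def naive_membership(
    text: str, kmer: str, max_mismatches: int, both_strands: bool = True
) -> SearchResult:
    """Membership by Hamming-neighbor enumeration plus substring scan.

    Neighbors substitute A/C/G/T only, so a reference window containing N
    (or the terminator) is never matched — the same contract as the index.
    """
    k = len(kmer)
    patterns = [kmer]
    if both_strands:
        patterns.append(reverse_complement(kmer))
    if any(p in text for p in patterns):
        return SearchResult(True, True, frozenset(range(k)))
    if max_mismatches == 0:
        return SearchResult(False, False, frozenset())
    mismatch_at: set[int] = set()
    for strand, pat in enumerate(patterns):
        for j in range(k):
            for b in DNA:
                if b == pat[j]:
                    continue
                if pat[:j] + b + pat[j + 1 :] in text:
                    mismatch_at.add(j if strand == 0 else k - 1 - j)
    if not mismatch_at:
        return SearchResult(False, False, frozenset())
    if len(mismatch_at) == 1:
        concordant = frozenset(range(k)) - mismatch_at
    else:
        concordant = frozenset(range(k))
    return SearchResult(True, False, concordant)


def brute_smooth(
    record: ReadRecord, ref_text: str, params: SmoothingParams
) -> tuple[str, list[str]]:
    """Literal application of the four per-base rules, in order.

    Returns the smoothed quality string and per-base labels using the same
    vocabulary as the implementation.
    """
    seq = record.sequence.upper()
    n = len(seq)
    k = params.k
    q = [ord(c) - params.offset for c in record.quality]

    window_ok = {}
    results = {}
    for i in range(max(n - k + 1, 0)):
        ok = all(
            q[p] >= params.lower_threshold and seq[p] in DNA
            for p in range(i, i + k)
        )
        window_ok[i] = ok
        if ok:
            results[i] = naive_membership(
                ref_text, seq[i : i + k], params.max_mismatches, both_strands=True
            )

    out = list(q)
    labels = []
    for p in range(n):
        covering = [
            i
            for i in range(max(0, p - k + 1), min(p, n - k) + 1)
            if window_ok.get(i, False)
        ]
        if q[p] > params.higher_threshold:
            out[p] = params.replacement_quality
            labels.append("fastpath")
        elif q[p] < params.lower_threshold:
            labels.append("kept_low")
        elif not covering:
            labels.append("kept_uncovered")
        elif all(
            results[i].found and (p - i) in results[i].concordant_positions
            for i in covering
        ):
            out[p] = params.replacement_quality
            labels.append("smoothed")
        else:
            labels.append("kept_discordant")
    quality = "".join(chr(v + params.offset) for v in out)
    return quality, labels
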