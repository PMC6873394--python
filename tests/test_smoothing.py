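"""Per-base smoothing rule: thresholds, concordance, oracle equivalence."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from smoothq import (
    ReadRecord,
    Reference,
    build_index,
    phred_error_probability,
    queried_kmer_mask,
    smooth_read,
    smooth_stream,
)
from smoothq.smoothing import (
    FASTPATH,
    KEPT_DISCORDANT,
    KEPT_LOW,
    KEPT_UNCOVERED,
    SMOOTHED,
    SmoothingParams,
    SmoothingReport,
)
from oracles import brute_smooth

OFF = 33


def _rec(seq, quals):
    return ReadRecord("r", seq, "+", "".join(chr(q + OFF) for q in quals))


def _idx(seq):
    return build_index(Reference.from_sequences(["ref"], [seq]))


# ---------------------------------------------------------------------------
# Phred arithmetic


def test_phred_probability_of_apostrophe_quality():
    # "'" is code point 39, i.e. Phred+33 score 6
    assert ord("'") - OFF == 6
    assert round(phred_error_probability(6), 5) == 0.25119


@pytest.mark.parametrize("q,p", [(0, 1.0), (40, 1e-4), (10, 0.1)])
def test_phred_probability_closed_form(q, p):
    assert phred_error_probability(q) == pytest.approx(p)


def test_phred_probability_rejects_out_of_range():
    for q in (-1, 94):
        with pytest.raises(ValueError):
            phred_error_probability(q)


def test_params_validation():
    with pytest.raises(ValueError):
        SmoothingParams(k=1).validate()
    with pytest.raises(ValueError):
        SmoothingParams(lower_threshold=50, higher_threshold=40).validate()
    with pytest.raises(ValueError):
        SmoothingParams(max_mismatches=2).validate()
    SmoothingParams().validate()  # defaults are valid


# ---------------------------------------------------------------------------
# k-mer eligibility mask


def test_mask_excludes_windows_covering_a_low_quality_base():
    params = SmoothingParams(k=4, lower_threshold=6)
    quals = [30] * 10
    quals[5] = 2  # below L.T.
    mask = queried_kmer_mask(_rec("ACGTACGTAC", quals), params)
    assert mask.tolist() == [True, True, False, False, False, False, True]


def test_mask_all_queried_when_clean():
    params = SmoothingParams(k=4)
    mask = queried_kmer_mask(_rec("ACGTACGTAC", [30] * 10), params)
    assert mask.all() and len(mask) == 7


def test_mask_trims_low_quality_tail():
    # low-quality tail knocks out every window touching it
    params = SmoothingParams(k=5, lower_threshold=6)
    quals = [30] * 6 + [2] * 6
    mask = queried_kmer_mask(_rec("ACGTACGTACGT", quals), params)
    assert mask.tolist() == [True, True] + [False] * 6


def test_mask_excludes_windows_with_n():
    params = SmoothingParams(k=4)
    mask = queried_kmer_mask(_rec("ACGNACGTAC", [30] * 10), params)
    assert mask.tolist() == [False, False, False, False, True, True, True]


def test_mask_empty_for_short_reads():
    params = SmoothingParams(k=32)
    assert queried_kmer_mask(_rec("ACGT", [30] * 4), params).size == 0


@given(st.data())
def test_raising_lower_threshold_never_adds_queried_kmers(data):
    n = data.draw(st.integers(8, 40))
    seq = data.draw(st.text(alphabet="ACGTN", min_size=n, max_size=n))
    quals = data.draw(st.lists(st.integers(0, 41), min_size=n, max_size=n))
    rec = _rec(seq, quals)
    counts = []
    for lt in (0, 5, 10, 20):
        params = SmoothingParams(k=5, lower_threshold=lt, higher_threshold=41)
        counts.append(int(queried_kmer_mask(rec, params).sum()))
    assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------------------
# smooth_read rules


def test_read_contained_in_reference_fully_smoothed():
    ref = "ACGTTTGACAGATTACAGGT"
    idx = _idx(ref)
    params = SmoothingParams(k=5, lower_threshold=6, higher_threshold=40)
    rec = _rec(ref[2:14], [30] * 12)
    out, labels = smooth_read(rec, idx, params)
    assert out.quality == params.replacement_char * 12
    assert set(labels) == {SMOOTHED}
    assert out.sequence == rec.sequence and out.header == rec.header


def test_single_substitution_blocks_only_its_windows():
    # a mismatch keeps its own quality; bases covered by at least one clean
    # k-mer are still smoothed
    ref = "ACGTTTGACAGATTACAGGTACCA"
    idx = _idx(ref)
    k = 5
    params = SmoothingParams(k=k, max_mismatches=0, lower_threshold=0, higher_threshold=93)
    read_seq = list(ref[:16])
    p = 8
    read_seq[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read_seq[p]]
    rec = _rec("".join(read_seq), [30] * 16)
    out, labels = smooth_read(rec, idx, params)
    # every window covering p contains the mismatch, so p itself is kept
    assert labels[p] == KEPT_DISCORDANT
    # positions far from p are covered by clean exact windows only
    assert labels[0] == SMOOTHED and labels[15] == SMOOTHED
    assert out.quality[p] == rec.quality[p]


def test_empty_dictionary_with_max_threshold_is_identity():
    idx = _idx("TTTTTTTTTTTTTTTTTTTT")
    params = SmoothingParams(k=5, higher_threshold=93)
    rec = _rec("ACGAGCGATTAC".replace("T", "C"), [30, 41, 6, 93, 0, 30, 30, 30, 30, 30, 30, 30])
    out, labels = smooth_read(rec, idx, params)
    assert out.quality == rec.quality
    assert SMOOTHED not in labels and FASTPATH not in labels


def test_fast_path_replaces_above_higher_threshold_only():
    idx = _idx("TTTTTTTTTT")  # read k-mers absent
    params = SmoothingParams(k=4, lower_threshold=6, higher_threshold=40)
    quals = [41, 40, 39, 2, 41, 30, 30, 30]
    rec = _rec("ACGACGAC", quals)
    out, labels = smooth_read(rec, idx, params)
    assert labels[0] == FASTPATH and out.quality[0] == params.replacement_char
    assert labels[4] == FASTPATH
    assert labels[1] != FASTPATH and out.quality[1] == rec.quality[1]  # exactly H.T.
    assert labels[3] == KEPT_LOW and out.quality[3] == rec.quality[3]


def test_short_read_kept_uncovered():
    idx = _idx("ACGTACGTACGT")
    params = SmoothingParams(k=32)
    rec = _rec("ACGTACGT", [30] * 8)
    out, labels = smooth_read(rec, idx, params)
    assert out.quality == rec.quality
    assert set(labels) == {KEPT_UNCOVERED}


@given(st.data())
def test_smooth_read_matches_bruteforce_rules(data):
    ref_seq = data.draw(st.text(alphabet="ACGT", min_size=30, max_size=200))
    reference = Reference.from_sequences(["r"], [ref_seq])
    idx = build_index(reference)
    k = data.draw(st.integers(3, 8))
    m = data.draw(st.integers(0, 1))
    n = data.draw(st.integers(5, 50))
    # mix of reference-derived and random read content
    if data.draw(st.booleans()) and len(ref_seq) >= n:
        start = data.draw(st.integers(0, len(ref_seq) - n))
        seq = ref_seq[start : start + n]
    else:
        seq = data.draw(st.text(alphabet="ACGTN", min_size=n, max_size=n))
    quals = data.draw(st.lists(st.integers(0, 45), min_size=n, max_size=n))
    params = SmoothingParams(
        k=k,
        max_mismatches=m,
        lower_threshold=data.draw(st.integers(0, 10)),
        higher_threshold=data.draw(st.integers(35, 93)),
    )
    rec = _rec(seq, quals)
    out, labels = smooth_read(rec, idx, params)
    want_quality, want_labels = brute_smooth(rec, reference.text, params)
    assert out.quality == want_quality
    assert labels == want_labels


@given(st.data())
def test_untouchability_and_alphabet_bound(data):
    ref_seq = data.draw(st.text(alphabet="ACGT", min_size=20, max_size=100))
    idx = build_index(Reference.from_sequences(["r"], [ref_seq]))
    n = data.draw(st.integers(4, 40))
    seq = data.draw(st.text(alphabet="ACGT", min_size=n, max_size=n))
    quals = data.draw(st.lists(st.integers(0, 50), min_size=n, max_size=n))
    params = SmoothingParams(k=4, lower_threshold=6, higher_threshold=40)
    rec = _rec(seq, quals)
    out, labels = smooth_read(rec, idx, params)
    # low-quality positions are untouched (fast path cannot fire below L.T.
    # because L.T. <= H.T.)
    for p, q in enumerate(quals):
        if q < params.lower_threshold:
            assert out.quality[p] == rec.quality[p]
            assert labels[p] == KEPT_LOW
    # output quality alphabet is bounded by input alphabet + replacement
    assert set(out.quality) <= set(rec.quality) | {params.replacement_char}
    assert out.sequence == rec.sequence


# ---------------------------------------------------------------------------
# smooth_stream


def test_stream_preserves_order_and_counters_partition(rng):
    ref_seq = "".join(rng.choice(list("ACGT"), size=3000))
    idx = _idx(ref_seq)
    params = SmoothingParams(k=8)
    records = []
    for i in range(100):
        start = int(rng.integers(0, len(ref_seq) - 50))
        quals = rng.integers(2, 42, size=50)
        records.append(
            ReadRecord(f"r{i}", ref_seq[start : start + 50], "+",
                       "".join(chr(q + OFF) for q in quals))
        )
    out_iter, report = smooth_stream(records, idx, params)
    out = list(out_iter)
    assert [r.header for r in out] == [f"r{i}" for i in range(100)]
    assert report.reads_processed == 100
    assert report.bases_total == 5000
    assert report.kmers_found <= report.kmers_queried


def test_stream_identity_configuration_smooths_nothing(rng):
    idx = _idx("T" * 200)  # shares no k-mer with ACG-only reads
    params = SmoothingParams(k=6, higher_threshold=93)
    records = [
        ReadRecord(f"r{i}", "ACGACGACGACG", "+", "IIIIIIIIIIII") for i in range(10)
    ]
    out_iter, report = smooth_stream(records, idx, params)
    out = list(out_iter)
    assert report.bases_smoothed == 0 and report.bases_fastpathed == 0
    assert [r.quality for r in out] == [r.quality for r in records]


def test_report_invariant_checks():
    rep = SmoothingReport(bases_smoothed=3, bases_kept_low_quality=2, bases_fastpathed=1)
    assert rep.bases_total == 6
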