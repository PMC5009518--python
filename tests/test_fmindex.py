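"""Bidirectional BWT index: worked examples, oracle equivalence and
structural invariants."""

import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adaseed import ReadSet, ReadSetError, build_index
from adaseed import dna

import oracle

read_sets = st.lists(
    st.text(alphabet="ACGT", min_size=8, max_size=8), min_size=1, max_size=12
)


class TestWorkedExamples:
    def test_bwt_length_counts_one_sentinel_per_read(self, tiny_index):
        assert tiny_index.fwd.size == 2 * 4
        assert tiny_index.rev.size == 2 * 4

    def test_depth_counts_both_strands(self, tiny_index):
        assert tiny_index.isr_of("ACG").depth == 2  # ACG + its RC "CGT"
        assert tiny_index.isr_of("CG").depth == 4   # self-complementary window
        assert tiny_index.isr_of("AAAA").depth == 0

    def test_backward_extension_reaches_cg(self, tiny_index):
        isr = tiny_index.empty_range()
        for c in "GC":  # extend with G then C
            isr = tiny_index.extend_backward(isr, c)
        assert isr.fwd_hi - isr.fwd_lo == 2

    def test_prefix_lookup_reports_both_orientations(self, tiny_index):
        ix = tiny_index
        assert (0, False) in ix.reads_with_prefix(ix.isr_of("AC"))
        assert ix.reads_with_prefix(ix.isr_of("CG")) == {(1, False), (0, True)}
        assert ix.reads_with_prefix(ix.isr_of("ACGT")) == set()

    def test_symbol_histogram_matches_input(self):
        rng = random.Random(7)
        reads = oracle.random_reads(rng, 100, 20)
        ix = build_index(ReadSet.from_strings(reads))
        sym = ix.fwd.bwt & 7
        assert int((sym == dna.SENT).sum()) == 100
        joined = "".join(reads)
        for code, ch in [(1, "A"), (2, "C"), (3, "G"), (4, "T")]:
            assert int((sym == code).sum()) == joined.count(ch)


class TestErrors:
    def test_unequal_read_lengths_rejected_naming_record(self):
        with pytest.raises(ReadSetError, match="read 1"):
            ReadSet.from_strings(["ACGT", "ACG"])

    def test_empty_read_set_rejected(self):
        with pytest.raises(ReadSetError):
            ReadSet.from_strings([])

    def test_non_base_extension_rejected(self, tiny_index):
        with pytest.raises(ValueError):
            tiny_index.extend_backward(tiny_index.empty_range(), "N")

    def test_recover_out_of_range(self, tiny_index):
        with pytest.raises(IndexError):
            tiny_index.recover_read(2)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(read_sets)
def test_depth_matches_brute_force_for_all_read_substrings(reads):
    """depth(ISR(P)) equals naive double-strand occurrence counting for
    every substring P of every read."""
    ix = build_index(ReadSet.from_strings(reads))
    seen = set()
    for r in reads:
        for i in range(len(r)):
            for j in range(i + 1, len(r) + 1):
                seen.add(r[i:j])
    for p in seen:
        assert ix.isr_of(p).depth == oracle.double_strand_depth(reads, p)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(read_sets, st.text(alphabet="ACGT", min_size=1, max_size=8))
def test_intervals_match_suffix_array_oracle(reads, pattern):
    """All three ISR intervals agree with a brute-force suffix sort."""
    ix = build_index(ReadSet.from_strings(reads))
    isr = ix.isr_of(pattern)
    fwd_entries = oracle.suffix_entries(reads)
    rev_entries = oracle.suffix_entries([r[::-1] for r in reads])
    rc = oracle.revcomp(pattern)
    comp = rc[::-1]
    for got, want in [
        ((isr.fwd_lo, isr.fwd_hi), oracle.sa_interval(fwd_entries, pattern)),
        ((isr.rc_lo, isr.rc_hi), oracle.sa_interval(fwd_entries, rc)),
        ((isr.rev_lo, isr.rev_hi), oracle.sa_interval(rev_entries, comp)),
    ]:
        if want[1] > want[0]:
            assert got == want
        else:
            assert got[1] <= got[0]


@settings(max_examples=40, deadline=None, derandomize=True)
@given(read_sets, st.text(alphabet="ACGT", min_size=1, max_size=8))
def test_forward_and_backward_extension_commute(reads, pattern):
    """Building ISR(P) left-to-right equals building it right-to-left."""
    ix = build_index(ReadSet.from_strings(reads))
    back = ix.isr_of(pattern)  # backward extensions
    fwd = ix.empty_range()
    for c in pattern:
        fwd = ix.extend_forward(fwd, c)
    for f in ("fwd_lo", "fwd_hi", "rc_lo", "rc_hi", "rev_lo", "rev_hi"):
        assert getattr(back, f) == getattr(fwd, f), f
    # mixed order: backward then forward
    k = len(pattern) // 2
    mixed = ix.empty_range()
    for c in reversed(pattern[:k]):
        mixed = ix.extend_backward(mixed, c)
    for c in pattern[k:]:
        mixed = ix.extend_forward(mixed, c)
    assert (mixed.fwd_lo, mixed.fwd_hi) == (back.fwd_lo, back.fwd_hi)
    assert mixed.depth == back.depth


@settings(max_examples=40, deadline=None, derandomize=True)
@given(read_sets, st.text(alphabet="ACGT", min_size=1, max_size=6),
       st.sampled_from("ACGT"))
def test_depth_monotone_under_extension(reads, pattern, x):
    ix = build_index(ReadSet.from_strings(reads))
    isr = ix.isr_of(pattern)
    assert ix.extend_backward(isr, x).depth <= isr.depth
    assert ix.extend_forward(isr, x).depth <= isr.depth


def test_recover_read_round_trips_sequence_and_quality():
    rng = random.Random(99)
    reads = oracle.random_reads(rng, 60, 17)
    quals = [[rng.randrange(2, 41) for _ in r] for r in reads]
    cutoff = 20
    ix = build_index(ReadSet.from_strings(reads, quals=quals), quality_cutoff=cutoff)
    for i, r in enumerate(reads):
        seq, hq = ix.recover_read(i)
        assert seq == r
        assert hq.tolist() == [q >= cutoff for q in quals[i]]


def test_all_low_quality_read_has_zero_bitmask():
    reads = ["ACGTACGT", "TTTTACGT"]
    quals = [[2] * 8, [40] * 8]
    ix = build_index(ReadSet.from_strings(reads, quals=quals), quality_cutoff=20)
    assert not ix.recover_read(0)[1].any()
    assert ix.recover_read(1)[1].all()


def test_reads_with_prefix_matches_direct_scan(random_indexed_reads):
    reads, ix = random_indexed_reads
    rng = random.Random(5)
    for _ in range(50):
        r = rng.choice(reads)
        k = rng.randrange(1, len(r) + 1)
        p = r[:k]
        want = set()
        for i, q in enumerate(reads):
            if q.startswith(p):
                want.add((i, False))
            if oracle.revcomp(q).startswith(p):
                want.add((i, True))
        assert ix.reads_with_prefix(ix.isr_of(p)) == want


def test_index_save_load_round_trip(tmp_path, random_indexed_reads):
    from adaseed.fmindex import BidirectionalIndex

    reads, ix = random_indexed_reads
    path = str(tmp_path / "toy.idx.npz")
    ix.save(path)
    ix2 = BidirectionalIndex.load(path)
    assert (ix2.n, ix2.m) == (ix.n, ix.m)
    p = reads[0][3:15]
    a, b = ix.isr_of(p), ix2.isr_of(p)
    assert (a.fwd_lo, a.fwd_hi, a.depth) == (b.fwd_lo, b.fwd_hi, b.depth)
    assert ix2.recover_read(5)[0] == reads[5]
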