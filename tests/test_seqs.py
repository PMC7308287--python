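"""Sequence types, FASTA/interval I/O, masking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spacerome import (
    AlphabetError,
    FastaParseError,
    GenomeWithArrays,
    Interval,
    IntervalFormatError,
    NucSequence,
    SpacerRecord,
    dedup_spacers,
    load_fasta,
    load_intervals,
    masked_positions,
    merge_intervals,
    reverse_complement,
    write_fasta,
)
from spacerome.seqs import flag_short_spacers

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


@pytest.mark.parametrize(
    "seq,expected",
    [("AAG", "CTT"), ("ACGT", "ACGT"), ("N", "N"), ("ACN", "NGT")],
)
def test_reverse_complement_examples(seq, expected):
    assert reverse_complement(seq) == expected


@settings(derandomize=True, max_examples=100)
@given(dna)
def test_reverse_complement_involution_and_composition(seq):
    rc = reverse_complement(seq)
    assert reverse_complement(rc) == seq
    assert len(rc) == len(seq)
    # A<->T and C<->G pair counts are swapped, multiset preserved
    assert rc.count("A") == seq.count("T") and rc.count("C") == seq.count("G")


def test_reverse_complement_rejects_bad_alphabet():
    with pytest.raises(AlphabetError):
        reverse_complement("ACGU")


def test_fasta_round_trip(tmp_path, rng):
    recs = [
        NucSequence("a", "ACGTN"),
        NucSequence("b", "".join(rng.choice(list("ACGT"), size=211))),
    ]
    p = tmp_path / "x.fasta"
    write_fasta(p, recs)
    back = load_fasta(p)
    assert [(r.id, r.seq) for r in back] == [(r.id, r.seq) for r in recs]


def test_fasta_lowercase_normalized(tmp_path):
    p = tmp_path / "x.fasta"
    p.write_text(">r1\nacgt\n")
    (rec,) = load_fasta(p)
    assert rec.seq == "ACGT"


def test_fasta_errors(tmp_path):
    p = tmp_path / "bad.fasta"
    p.write_text(">r1\nACGX\n")
    with pytest.raises(AlphabetError, match="r1"):
        load_fasta(p)
    p.write_text(">r1\nACG\n>r1\nTTT\n")
    with pytest.raises(FastaParseError, match="duplicate"):
        load_fasta(p)
    p.write_text("ACGT\n")
    with pytest.raises(FastaParseError, match="line 1"):
        load_fasta(p)


def test_load_intervals_merges_and_validates(tmp_path):
    p = tmp_path / "iv.tsv"
    p.write_text("s1\t10\t20\ns1\t15\t25\n")
    assert load_intervals(p) == [Interval("s1", 10, 25)]
    p.write_text("s1\t5\t5\n")
    with pytest.raises(IntervalFormatError):
        load_intervals(p)
    p.write_text("")
    assert load_intervals(p) == []


@settings(derandomize=True, max_examples=60)
@given(
    st.lists(
        st.tuples(st.sampled_from(["a", "b"]), st.integers(0, 50), st.integers(1, 30)),
        max_size=12,
    )
)
def test_merge_intervals_idempotent_order_independent(raw):
    ivs = [Interval(s, lo, lo + w) for s, lo, w in raw]
    merged = merge_intervals(ivs)
    assert merge_intervals(merged) == merged
    assert merge_intervals(list(reversed(ivs))) == merged
    # merged intervals are disjoint per seq_id
    for a, b in zip(merged, merged[1:]):
        if a.seq_id == b.seq_id:
            assert a.end <= b.start


def test_masked_positions(tiny_genome):
    masks = masked_positions(tiny_genome)
    assert masks["chr"].sum() == 60 and masks["pls"].sum() == 30
    g = GenomeWithArrays("g", [NucSequence("s1", "A" * 100)],
                         [Interval("s1", 0, 100)])
    assert masked_positions(g)["s1"].all()
    g2 = GenomeWithArrays("g", [NucSequence("s1", "A" * 100)], [])
    assert not masked_positions(g2)["s1"].any()
    g3 = GenomeWithArrays(
        "g", [NucSequence("s1", "A" * 100)],
        [Interval("s1", 10, 20), Interval("s1", 30, 40)])
    assert masked_positions(g3)["s1"].sum() == 20


def test_genome_validation():
    with pytest.raises(IntervalFormatError, match="unknown"):
        GenomeWithArrays("g", [NucSequence("s1", "ACGT")],
                         [Interval("s2", 0, 2)])
    with pytest.raises(IntervalFormatError, match="exceeds"):
        GenomeWithArrays("g", [NucSequence("s1", "ACGT")],
                         [Interval("s1", 0, 10)])
    g = GenomeWithArrays("g", [NucSequence("s1", "A" * 50)],
                         [Interval("s1", 0, 10), Interval("s1", 5, 20)])
    assert g.arrays == [Interval("s1", 0, 20)]


def test_spacer_records():
    with pytest.raises(AlphabetError):
        SpacerRecord("ACGN")
    sps = [SpacerRecord("ACGTACGT", count=3), SpacerRecord("ACGTACGT", count=2),
           SpacerRecord("TTTTTTTT")]
    dd = dedup_spacers(sps)
    assert len(dd) == 2 and dd[0].count == 5
    assert set(flag_short_spacers(dd, k_max=9)) == {"ACGTACGT", "TTTTTTTT"}
    assert flag_short_spacers(dd, k_max=8) == []
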