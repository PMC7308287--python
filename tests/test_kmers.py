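"""k-mer enumeration, exact search (vs brute-force oracle) and the
pseudo-count match statistic."""

from fractions import Fraction

import numpy as np
import pytest

from spacerome import (
    NucSequence,
    SpacerRecord,
    TargetSet,
    enumerate_kmers,
    find_occurrences,
    find_occurrences_naive,
    match_curve,
    match_fraction,
    match_indicators,
    reverse_complement,
    spacer_has_match,
    weighted_match_fraction,
)
from spacerome.kmers import KmerQuery, ParameterError
from tests.conftest import random_seq


def test_enumerate_kmers_examples():
    assert enumerate_kmers(SpacerRecord("ACGTACGT"), 8).kmers == {"ACGTACGT"}
    assert enumerate_kmers(SpacerRecord("A" * 10), 8).kmers == {"A" * 8}
    q = enumerate_kmers(SpacerRecord(random_seq(np.random.default_rng(0), 33)), 22)
    assert 1 <= len(q.kmers) <= 12
    assert all(len(km) == 22 for km in q.kmers)
    assert enumerate_kmers(SpacerRecord("ACGT"), 8).kmers == frozenset()
    # windows containing N are never generated
    assert enumerate_kmers("ACNGT", 3).kmers == frozenset()
    assert enumerate_kmers("ACNGTT", 3).kmers == {"GTT"}
    with pytest.raises(ParameterError):
        enumerate_kmers(SpacerRecord("ACGT"), 0)


def test_find_occurrences_examples():
    t = TargetSet.from_sequences("t", [NucSequence("s", "TTAAGTT")])
    assert find_occurrences(KmerQuery(3, frozenset({"AAG"})), t) == [("s", 2, "+")]
    t2 = TargetSet.from_sequences("t", [NucSequence("s", "CTT")])
    assert find_occurrences(KmerQuery(3, frozenset({"AAG"})), t2) == [("s", 0, "-")]


def test_find_occurrences_respects_mask():
    t = TargetSet.from_sequences("t", [NucSequence("s", "TTAAGTT")])
    t.mask["s"] = np.zeros(7, dtype=bool)
    t.mask["s"][4] = True  # overlaps the AAG span at 2..5
    assert find_occurrences(KmerQuery(3, frozenset({"AAG"})), t) == []


def test_indexed_search_equals_naive_scan(rng):
    """Randomized oracle equivalence on small instances."""
    for _ in range(60):
        k = int(rng.integers(3, 12))
        target = NucSequence("t", random_seq(rng, int(rng.integers(50, 300))))
        spacer = random_seq(rng, int(rng.integers(k, 40)))
        # plant the spacer sometimes so hits are common
        seq = target.seq
        if rng.random() < 0.5 and len(seq) > len(spacer):
            pos = int(rng.integers(0, len(seq) - len(spacer)))
            seq = seq[:pos] + spacer + seq[pos + len(spacer):]
        tset = TargetSet.from_sequences("t", [NucSequence("t", seq)])
        if rng.random() < 0.5:
            m = np.zeros(len(seq), dtype=bool)
            a = int(rng.integers(0, len(seq)))
            m[a:a + int(rng.integers(1, 30))] = True
            tset.mask["t"] = m
        q = enumerate_kmers(SpacerRecord(spacer), k)
        assert find_occurrences(q, tset) == find_occurrences_naive(q, tset)


def test_spacer_has_match_cases(rng):
    genome = random_seq(rng, 500)
    t = TargetSet.from_sequences("t", [NucSequence("s", genome)])
    sp = SpacerRecord(genome[100:130])
    assert spacer_has_match(sp, 22, t)
    assert not spacer_has_match(SpacerRecord(random_seq(rng, 25)), 26, t)
    # only hit masked -> no match
    t.mask["s"] = np.zeros(500, dtype=bool)
    t.mask["s"][100:130] = True
    unique = SpacerRecord(genome[100:130])
    ind = match_indicators([unique], t, [30])
    assert not ind[0, 0]


@pytest.mark.parametrize(
    "m,N,expected",
    [(0, 0, Fraction(1, 2)), (10, 10, Fraction(11, 12)),
     (812, 10555, Fraction(813, 10557)), (0, 98, Fraction(1, 100))],
)
def test_match_fraction_exact(m, N, expected):
    assert match_fraction(m, N) == expected


def test_match_fraction_errors():
    with pytest.raises(ParameterError):
        match_fraction(5, 4)
    with pytest.raises(ParameterError):
        match_fraction(-1, 4)


def test_weighted_fraction_reduces_and_expands(rng):
    genome = random_seq(rng, 400)
    t = TargetSet.from_sequences("t", [NucSequence("s", genome)])
    sps = [SpacerRecord(genome[50:80], count=100),
           SpacerRecord(random_seq(rng, 30), count=1)]
    assert weighted_match_fraction(sps, 22, t) == Fraction(101, 103)
    ones = [SpacerRecord(sp.seq) for sp in sps]
    assert weighted_match_fraction(ones, 22, t) == Fraction(2, 4)
    # expansion oracle: repeat each spacer `count` times, count unweighted
    expanded = [SpacerRecord(sp.seq) for sp in sps for _ in range(sp.count)]
    ind = match_indicators(expanded, t, [22])[:, 0]
    assert weighted_match_fraction(sps, 22, t) == Fraction(int(ind.sum()) + 1,
                                                           len(expanded) + 2)


def test_match_curve_containment_and_floor(rng):
    virome = NucSequence("v", random_seq(rng, 3000))
    t = TargetSet.from_sequences("virome", [virome])
    sps = [SpacerRecord(virome.seq[i * 40:i * 40 + 30]) for i in range(10)]
    curve = match_curve(sps, t, k_values=range(8, 23))
    assert (curve.m_per_k == 10).all()
    t2 = TargetSet.from_sequences("poly", [NucSequence("a", "A" * 100)])
    sps2 = [SpacerRecord("C" * 30) for _ in range(1)] + [SpacerRecord("CG" * 15)]
    c2 = match_curve(sps2, t2, k_values=[8, 12])
    assert (c2.m_per_k == 0).all()
    assert np.allclose(c2.fraction_per_k, 1 / (2 + 2))


def test_monotonicity_strand_symmetry_mask_monotonicity(rng):
    for _ in range(10):
        target = NucSequence("t", random_seq(rng, 800))
        sps = [SpacerRecord(random_seq(rng, 30)) for _ in range(8)]
        if rng.random() < 0.5:  # plant some
            sps[0] = SpacerRecord(target.seq[5:35])
        t = TargetSet.from_sequences("t", [target])
        kv = list(range(5, 15))
        curve = match_curve(sps, t, k_values=kv)
        assert (np.diff(curve.m_per_k) <= 0).all()
        # strand symmetry: reverse-complement every target
        t_rc = TargetSet.from_sequences(
            "t", [NucSequence("t", reverse_complement(target.seq))])
        assert (match_indicators(sps, t, kv)
                == match_indicators(sps, t_rc, kv)).all()
        # masking monotonicity
        m1 = np.zeros(800, dtype=bool)
        m1[100:300] = True
        m2 = m1.copy()
        m2[0:500] = True
        t_m1 = TargetSet("t", [target], {"t": m1})
        t_m2 = TargetSet("t", [target], {"t": m2})
        i1 = match_indicators(sps, t_m1, kv)
        i2 = match_indicators(sps, t_m2, kv)
        assert not (i2 & ~i1).any()


def test_pseudocount_bounds(rng):
    target = NucSequence("t", random_seq(rng, 500))
    sps = [SpacerRecord(random_seq(rng, 25)) for _ in range(5)]
    curve = match_curve(sps, TargetSet.from_sequences("t", [target]),
                        k_values=range(6, 20))
    f = curve.fraction_per_k
    assert (f >= 1 / 7).all() and (f <= 6 / 7).all()


def test_own_source_window_exclusion(rng):
    """A spacer whose sequence occurs only at its own source window does not
    count as a self match when the source is excluded; a second copy does."""
    core = random_seq(rng, 30)
    filler = random_seq(rng, 100)
    single = filler[:50] + core + filler[50:]
    double = single + random_seq(rng, 20) + core
    sp_single = SpacerRecord(core, source=("s", 50, "+"))
    t_single = TargetSet.from_sequences("g", [NucSequence("s", single)])
    t_double = TargetSet.from_sequences("g", [NucSequence("s", double)])
    assert not match_indicators([sp_single], t_single, [22],
                                exclude_source=True)[0, 0]
    assert match_indicators([sp_single], t_single, [22])[0, 0]
    assert match_indicators([sp_single], t_double, [22],
                            exclude_source=True)[0, 0]
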