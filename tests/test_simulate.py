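"""Synthetic scenario generator: reproducibility, truth bookkeeping,
containment properties and parameter plumbing."""

import filecmp

import numpy as np
import pytest

from spacerome import (
    SpaceromeScenario,
    TargetSet,
    generate_adaptation_dataset,
    generate_scenario,
    match_curve,
    pam_table,
)
from spacerome.simulate import CapacityError

SMALL = dict(host_length=100_000, n_viruses=2, virus_length=20_000,
             n_proviruses=1, provirus_length=5_000, array_length=1_000,
             n_spacers=200)


def test_generation_reproducible_byte_identical(tmp_path):
    sc = SpaceromeScenario(seed=7, **SMALL)
    d1, d2 = generate_scenario(sc), generate_scenario(sc)
    a, b = tmp_path / "a", tmp_path / "b"
    d1.write(a)
    d2.write(b)
    for name in ("host.fasta", "virome.fasta", "spacers.fasta",
                 "arrays.tsv", "truth.tsv"):
        assert filecmp.cmp(a / name, b / name, shallow=False), name
    d3 = generate_scenario(SpaceromeScenario(seed=8, **SMALL))
    assert d3.genome.sequences[0].seq != d1.genome.sequences[0].seq


def test_truth_conservation_and_uniqueness():
    d = generate_scenario(SpaceromeScenario(seed=3, **SMALL))
    counts = d.truth.origin_counts()
    assert sum(counts.values()) == 200
    assert len(d.truth.table) == len(d.spacers) == 200
    assert len({sp.seq for sp in d.spacers}) == 200
    assert set(d.truth.table["origin"]) <= {"virus", "self", "dark"}
    assert list(d.truth.table["spacer_id"]) == [sp.spacer_id for sp in d.spacers]


def test_all_virus_verbatim_containment():
    sc = SpaceromeScenario(seed=5, f_virus=1.0, f_self=0.0, mu=0.0, **SMALL)
    d = generate_scenario(sc)
    vir_seqs = {v.id: v.seq for v in d.virome}
    for sp, row in zip(d.spacers, d.truth.table.itertuples()):
        assert row.origin == "virus" and row.n_mutations == 0
        assert vir_seqs[row.source_id][row.source_start:
                                       row.source_start + len(sp)] == sp.seq
    curve = match_curve(d.spacers, TargetSet.from_sequences("v", d.virome),
                        k_values=[8, 15, 22])
    assert (curve.m_per_k == 200).all()


def test_all_dark_no_long_matches():
    sc = SpaceromeScenario(seed=6, f_virus=0.0, f_self=0.0, mu=0.0, **SMALL)
    d = generate_scenario(sc)
    curve = match_curve(d.spacers, TargetSet.from_sequences("v", d.virome),
                        k_values=[22])
    assert curve.m_per_k[0] == 0


def test_self_spacers_avoid_array_and_match_host():
    sc = SpaceromeScenario(seed=9, f_virus=0.0, f_self=1.0, mu=0.0, **SMALL)
    d = generate_scenario(sc)
    (array,) = d.genome.arrays
    host = d.genome.sequences[0].seq
    for sp, row in zip(d.spacers, d.truth.table.itertuples()):
        s = row.source_start
        assert s + len(sp) <= array.start or s >= array.end
        assert host[s:s + len(sp)] == sp.seq


def test_mutation_counts_recorded():
    sc = SpaceromeScenario(seed=2, f_virus=1.0, f_self=0.0, mu=0.2, **SMALL)
    d = generate_scenario(sc)
    nm = d.truth.table["n_mutations"].to_numpy()
    assert nm.sum() > 0
    assert abs(nm.mean() - 0.2 * 32) < 3 * np.sqrt(0.2 * 0.8 * 32 / 200)


def test_capacity_error():
    with pytest.raises(CapacityError):
        generate_scenario(SpaceromeScenario(
            seed=0, host_length=10_000, n_viruses=1, virus_length=6_000,
            n_proviruses=5, provirus_length=4_000))


def test_scenario_validation():
    with pytest.raises(ValueError):
        SpaceromeScenario(f_virus=0.9, f_self=0.3)
    with pytest.raises(ValueError):
        SpaceromeScenario(mu=0.7)
    with pytest.raises(ValueError):
        SpaceromeScenario(pam="AAGG")


def test_adaptation_counts_and_pam_planting():
    sc = SpaceromeScenario(seed=4, f_virus=1.0, f_self=0.0, mu=0.0,
                           pam="AAG", **SMALL)
    d0 = generate_adaptation_dataset(sc, counts_dispersion=0.0)
    assert all(sp.count == 1 for sp in d0.spacers)
    d = generate_adaptation_dataset(sc, counts_dispersion=3.0)
    counts = np.array([sp.count for sp in d.spacers])
    assert counts.min() >= 1 and counts.mean() > 2
    # spacers identical to the dispersion-0 dataset; only counts differ
    assert [sp.seq for sp in d.spacers] == [sp.seq for sp in d0.spacers]
    # every virus-derived protospacer carries the planted PAM upstream
    vir = {v.id: v.seq for v in d.virome}
    for row in d.truth.table.itertuples():
        assert vir[row.source_id][row.source_start - 3:row.source_start] == "AAG"
    tab = pam_table(d.spacers, d.virome)
    assert tab.top_pam == "AAG" and tab.top_fraction == 1.0
    with pytest.raises(ValueError):
        generate_adaptation_dataset(SpaceromeScenario(seed=1, **SMALL), 1.0)
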