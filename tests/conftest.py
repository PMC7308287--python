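import numpy as np
import pytest

from spacerome import GenomeWithArrays, Interval, NucSequence, SpacerRecord


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(20201014)


@pytest.fixture
def tiny_genome(rng):
    """Two-replicon host with one array interval on each."""
    chrom = random_seq(rng, 600)
    plasmid = random_seq(rng, 250)
    return GenomeWithArrays(
        genome_id="g1",
        sequences=[NucSequence("chr", chrom), NucSequence("pls", plasmid)],
        arrays=[Interval("chr", 100, 160), Interval("pls", 40, 70)],
    )


@pytest.fixture
def small_spacers(rng, tiny_genome):
    """Ten spacers copied verbatim from the tiny genome outside its arrays."""
    chrom = tiny_genome.sequence("chr").seq
    out = []
    for i in range(10):
        start = int(rng.integers(200, 560))
        out.append(
            SpacerRecord(chrom[start:start + 30], genome_id="g1",
                         spacer_id=f"s{i}", source=("chr", start, "+"))
        )
    return out
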