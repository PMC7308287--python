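"""Synthetic hosts, viromes and spaceromes with known origin composition.

The generator emulates the statistical structure the analysis is sensitive
to: a host genome that may carry integrated (diverged) provirus copies and
verbatim repeated elements, a repeat-free virome, and a spacer set that is a
stated mixture of virus-derived spacers (with per-base substitution noise),
self-derived spacers, and "dark" spacers with no source. A single reserved
array interval on the host acts as the mask carrier. For adaptation-style
datasets a PAM can be planted immediately 5' of every virus-derived
protospacer and spacers carry geometric redundancy counts.

Every draw flows from one seed; identical scenario + seed yields
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .seqs import (
    GenomeWithArrays,
    Interval,
    NucSequence,
    SpacerRecord,
    write_fasta,
    write_intervals,
    write_spacers_fasta,
)

_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class CapacityError(RuntimeError):
    """Requested insertions cannot be placed without overlap."""


@dataclass(frozen=True)
class SpaceromeScenario:
    """Parameters of one synthetic spacerome study.

    Defaults are the desk-scale regime used throughout: a 2 Mb host, a
    500 kb virome (10 x 50 kb), three 20 kb integrated proviruses diverged
    at 0.15 substitutions/base from their virome donors, and 1000 spacers of
    length 32 of which 8% are virus-derived (with 2% per-base copying noise)
    and 2% host-derived.
    """

    host_length: int = 2_000_000
    gc: float = 0.5
    n_viruses: int = 10
    virus_length: int = 50_000
    n_proviruses: int = 3
    provirus_length: int = 20_000
    provirus_divergence: float = 0.15
    n_repeat_elements: int = 0
    repeat_length: int = 2_000
    repeat_copies: int = 3
    array_length: int = 3_000
    n_spacers: int = 1_000
    spacer_length_dist: tuple[int, ...] = (32,)
    f_virus: float = 0.08
    f_self: float = 0.02
    mu: float = 0.02
    pam: str | None = None
    pam_fraction: float = 1.0
    seed: int = 0

    @property
    def f_dark(self) -> float:
        return 1.0 - self.f_virus - self.f_self

    def __post_init__(self) -> None:
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0,1)")
        if self.f_virus < 0 or self.f_self < 0 or self.f_dark < -1e-12:
            raise ValueError("origin fractions must be >= 0 and sum to <= 1")
        if not 0 <= self.mu <= 0.5:
            raise ValueError("mu must be in [0, 0.5]")
        if self.pam is not None and (
            len(self.pam) != 3 or set(self.pam) - set("ACGT")
        ):
            raise ValueError("pam must be a 3-mer over ACGT")
        if not 0 <= self.pam_fraction <= 1:
            raise ValueError("pam_fraction must be in [0,1]")
        if self.n_proviruses > 0 and self.provirus_length > self.virus_length:
            raise ValueError("provirus_length cannot exceed virus_length")


@dataclass
class SyntheticTruth:
    """Ground-truth origin labels and source coordinates per spacer."""

    table: pd.DataFrame  # spacer_id, origin, source_id, source_start, strand,
    #                      n_mutations, count

    def origin_counts(self) -> dict[str, int]:
        return self.table["origin"].value_counts().to_dict()


@dataclass
class ScenarioData:
    scenario: SpaceromeScenario
    genome: GenomeWithArrays
    virome: list[NucSequence]
    spacers: list[SpacerRecord]
    truth: SyntheticTruth
    provirus_intervals: list[Interval] = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(outdir / "host.fasta", self.genome.sequences)
        write_intervals(outdir / "arrays.tsv", self.genome.arrays)
        write_fasta(outdir / "virome.fasta", self.virome)
        write_spacers_fasta(
            outdir / "spacers.fasta", self.spacers,
            provenance=f"seed={self.scenario.seed}")
        if any(sp.count != 1 for sp in self.spacers):
            with open(outdir / "spacer_counts.tsv", "w") as fh:
                for sp in self.spacers:
                    fh.write(f"{sp.seq}\t{sp.count}\n")
        self.truth.table.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def _random_codes(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _to_str(codes: np.ndarray) -> str:
    return _ASCII[codes].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, codes: np.ndarray, rate: float
            ) -> tuple[np.ndarray, int]:
    """Substitute each base independently with the given rate, drawing
    uniformly among the three alternative bases."""
    if rate <= 0:
        return codes.copy(), 0
    out = codes.copy()
    hit = np.flatnonzero(rng.random(codes.size) < rate)
    if hit.size:
        # offset 1..3 from the current base, mod 4, is uniform over the others
        out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out, int(hit.size)


def _place_nonoverlapping(
    rng: np.random.Generator, host_length: int, lengths: Sequence[int],
    max_tries: int = 1000,
) -> list[int]:
    """Random non-overlapping start positions for segments of given lengths."""
    placed: list[tuple[int, int]] = []
    starts: list[int] = []
    for L in lengths:
        if L > host_length:
            raise CapacityError(f"segment of length {L} exceeds host")
        for _ in range(max_tries):
            s = int(rng.integers(0, host_length - L + 1))
            if all(s + L <= a or s >= b for a, b in placed):
                placed.append((s, s + L))
                starts.append(s)
                break
        else:
            raise CapacityError(
                f"could not place {len(lengths)} segments without overlap "
                f"in a {host_length} nt host"
            )
    return starts


def generate_scenario(scenario: SpaceromeScenario) -> ScenarioData:
    """Generate (host genome with a reserved array interval, virome, spacers,
    truth) under the scenario; fully reproducible from the seed."""
    sc = scenario
    ss = np.random.SeedSequence(sc.seed)
    rng_host, rng_vir, rng_plant, rng_sp = (
        np.random.default_rng(c) for c in ss.spawn(4))

    host = _random_codes(rng_host, sc.host_length, sc.gc)
    virome_codes = [
        _random_codes(rng_vir, sc.virus_length, sc.gc)
        for _ in range(sc.n_viruses)
    ]

    # --- choose spacer origins, lengths and sources -----------------------
    p = np.array([sc.f_virus, sc.f_self, max(sc.f_dark, 0.0)], dtype=float)
    origins = rng_sp.choice(
        np.array(["virus", "self", "dark"]),
        size=sc.n_spacers,
        p=p / p.sum(),
    )
    lengths = rng_sp.choice(
        np.asarray(sc.spacer_length_dist, dtype=np.int64), size=sc.n_spacers)

    min_start = 3 if sc.pam is not None else 0
    virus_sources: dict[int, tuple[int, int]] = {}
    pam_planted: dict[int, bool] = {}
    planted_starts: dict[int, list[int]] = {}
    for i in np.flatnonzero(origins == "virus"):
        L = int(lengths[i])
        planted = sc.pam is not None and rng_sp.random() < sc.pam_fraction
        for _try in range(1000):
            v = int(rng_sp.integers(sc.n_viruses))
            start = int(rng_sp.integers(min_start, sc.virus_length - L + 1))
            # planted PAM windows must not overwrite one another
            if not planted or all(
                abs(start - s) >= 3 for s in planted_starts.get(v, ())
            ):
                break
        else:
            raise CapacityError("could not place planted PAM windows")
        if planted:
            planted_starts.setdefault(v, []).append(start)
        virus_sources[int(i)] = (v, start)
        pam_planted[int(i)] = planted

    # plant PAMs into the virome before anything copies from it
    if sc.pam is not None:
        pam_codes = np.array([_CODE[c] for c in sc.pam], dtype=np.uint8)
        for i, (v, start) in virus_sources.items():
            if pam_planted[i]:
                virome_codes[v][start - 3:start] = pam_codes

    # --- plant array interval, proviruses and repeats into the host ------
    seg_lengths = (
        [sc.array_length]
        + [sc.provirus_length] * sc.n_proviruses
        + [sc.repeat_length] * (sc.n_repeat_elements * sc.repeat_copies)
    )
    starts = _place_nonoverlapping(rng_plant, sc.host_length, seg_lengths)
    array_iv = Interval("host", starts[0], starts[0] + sc.array_length)

    provirus_ivs: list[Interval] = []
    for p in range(sc.n_proviruses):
        s = starts[1 + p]
        v = int(rng_plant.integers(sc.n_viruses))
        dstart = int(rng_plant.integers(0, sc.virus_length - sc.provirus_length + 1))
        donor = virome_codes[v][dstart:dstart + sc.provirus_length]
        copy, _ = _mutate(rng_plant, donor, sc.provirus_divergence)
        host[s:s + sc.provirus_length] = copy
        provirus_ivs.append(Interval("host", s, s + sc.provirus_length))

    rep_starts = starts[1 + sc.n_proviruses:]
    for e in range(sc.n_repeat_elements):
        element = _random_codes(rng_plant, sc.repeat_length, sc.gc)
        for c in range(sc.repeat_copies):
            s = rep_starts[e * sc.repeat_copies + c]
            host[s:s + sc.repeat_length] = element

    # --- extract spacer sequences from the finished host/virome ----------
    records: list[SpacerRecord] = []
    rows: list[dict] = []
    seen: set[str] = set()
    for i in range(sc.n_spacers):
        L = int(lengths[i])
        origin = str(origins[i])
        for _attempt in range(100):
            nmut = 0
            if origin == "virus":
                if _attempt == 0 and i in virus_sources:
                    v, start = virus_sources[i]
                else:
                    while True:
                        v = int(rng_sp.integers(sc.n_viruses))
                        start = int(rng_sp.integers(min_start,
                                                    sc.virus_length - L + 1))
                        if not pam_planted.get(i) or all(
                            abs(start - s) >= 3
                            for s in planted_starts.get(v, ())
                        ):
                            break
                    virus_sources[i] = (v, start)
                    if pam_planted.get(i):
                        planted_starts.setdefault(v, []).append(start)
                        virome_codes[v][start - 3:start] = np.array(
                            [_CODE[c] for c in sc.pam], dtype=np.uint8)
                codes = virome_codes[v][start:start + L]
                codes, nmut = _mutate(rng_sp, codes, sc.mu)
                src = (f"virus{v}", start, "+")
            elif origin == "self":
                # uniform over host windows not overlapping the array
                while True:
                    start = int(rng_sp.integers(0, sc.host_length - L + 1))
                    if start + L <= array_iv.start or start >= array_iv.end:
                        break
                codes = host[start:start + L].copy()
                src = ("host", start, "+")
            else:
                codes = _random_codes(rng_sp, L, sc.gc)
                src = None
            seq = _to_str(codes)
            if seq not in seen:
                break
        else:
            raise CapacityError("could not generate a unique spacer")
        seen.add(seq)
        sid = f"sp{i}"
        records.append(
            SpacerRecord(seq, genome_id="synthetic_host", spacer_id=sid,
                         source=src))
        rows.append({
            "spacer_id": sid,
            "origin": origin,
            "source_id": src[0] if src else "",
            "source_start": src[1] if src else -1,
            "strand": src[2] if src else "",
            "n_mutations": nmut,
            "count": 1,
        })

    genome = GenomeWithArrays(
        genome_id="synthetic_host",
        sequences=[NucSequence("host", _to_str(host))],
        arrays=[array_iv],
    )
    virome = [
        NucSequence(f"virus{v}", _to_str(c)) for v, c in enumerate(virome_codes)
    ]
    truth = SyntheticTruth(pd.DataFrame(rows))
    return ScenarioData(sc, genome, virome, records, truth, provirus_ivs)


def generate_adaptation_dataset(
    scenario: SpaceromeScenario, counts_dispersion: float = 0.0,
) -> ScenarioData:
    """Scenario with redundancy counts emulating adaptation experiments.

    Counts are drawn per unique spacer from a geometric distribution with
    mean 1 + counts_dispersion; dispersion 0 gives all-ones counts and
    reduces to generate_scenario. Requires a planted PAM.
    """
    if scenario.pam is None:
        raise ValueError("adaptation datasets require a planted PAM")
    if counts_dispersion < 0:
        raise ValueError("counts_dispersion must be >= 0")
    data = generate_scenario(scenario)
    if counts_dispersion > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence(scenario.seed).spawn(5)[4])
        counts = rng.geometric(1.0 / (1.0 + counts_dispersion),
                               size=len(data.spacers))
        for sp, c in zip(data.spacers, counts):
            sp.count = int(c)
        data.truth.table["count"] = counts.astype(int)
    return data


def default_scenario(seed: int = 0, **overrides) -> SpaceromeScenario:
    return replace(SpaceromeScenario(seed=seed), **overrides)
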