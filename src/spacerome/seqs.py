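"""Core sequence types, FASTA/interval I/O and masking primitives.

All coordinates are 0-based, half-open ``[start, end)``. Genomes are handled
as collections of records (chromosome plus plasmids); windows never span
record boundaries. ``N`` is tolerated in genome sequences but any window
containing it is treated as unsearchable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GENOME_ALPHABET = frozenset("ACGTN")
SPACER_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte -> 2-bit code; N and anything else -> sentinel 255
_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE_LUT[_b] = _i


class AlphabetError(ValueError):
    """A sequence contains characters outside the allowed alphabet."""


class FastaParseError(ValueError):
    """Malformed FASTA input."""


class IntervalFormatError(ValueError):
    """Malformed or inconsistent interval annotation."""


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement over {A,C,G,T,N} (N maps to N)."""
    bad = set(seq) - GENOME_ALPHABET
    if bad:
        raise AlphabetError(f"non-nucleotide characters {sorted(bad)} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A,C,G,T -> 0..3, N -> 255)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[arr]


@dataclass(frozen=True)
class NucSequence:
    """A named nucleotide sequence, uppercase over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        if not seq:
            raise AlphabetError(f"record {self.id!r}: empty sequence")
        bad = set(seq) - GENOME_ALPHABET
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: characters outside ACGTN: {sorted(bad)}"
            )
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise IntervalFormatError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping/adjacent-overlapping intervals per seq_id.

    Idempotent and order-independent; intervals that merely touch
    (end == start) are kept separate since they share no position.
    """
    out: list[Interval] = []
    for iv in sorted(intervals):
        if out and out[-1].seq_id == iv.seq_id and iv.start < out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = Interval(iv.seq_id, out[-1].start, iv.end)
        else:
            out.append(Interval(iv.seq_id, iv.start, iv.end))
    return out


@dataclass
class GenomeWithArrays:
    """A host genome (all replicons) plus CRISPR-array intervals to mask."""

    genome_id: str
    sequences: list[NucSequence]
    arrays: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FastaParseError(f"genome {self.genome_id!r}: duplicate ids {dup}")
        lengths = {s.id: len(s) for s in self.sequences}
        for iv in self.arrays:
            if iv.seq_id not in lengths:
                raise IntervalFormatError(
                    f"array interval references unknown sequence {iv.seq_id!r}"
                )
            if iv.end > lengths[iv.seq_id]:
                raise IntervalFormatError(
                    f"array interval {iv.seq_id}:{iv.start}-{iv.end} exceeds "
                    f"sequence length {lengths[iv.seq_id]}"
                )
        self.arrays = merge_intervals(self.arrays)

    def sequence(self, seq_id: str) -> NucSequence:
        for s in self.sequences:
            if s.id == seq_id:
                return s
        raise KeyError(seq_id)


@dataclass
class SpacerRecord:
    """One spacer with its source genome/array identity and redundancy count.

    ``source`` optionally records where the sequence was copied from, as
    (seq_id, start, strand); control generators and the simulator fill it in
    so self-searches can exclude a spacer's own window where appropriate.
    """

    seq: str
    genome_id: str = ""
    array_id: str | None = None
    count: int = 1
    spacer_id: str = ""
    source: tuple[str, int, str] | None = None

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        bad = set(seq) - SPACER_ALPHABET
        if bad:
            raise AlphabetError(
                f"spacer {self.spacer_id or seq[:12]!r}: characters outside "
                f"ACGT: {sorted(bad)}"
            )
        if self.count < 1:
            raise ValueError("spacer count must be >= 1")
        self.seq = seq

    def __len__(self) -> int:
        return len(self.seq)


def flag_short_spacers(spacers: Sequence[SpacerRecord], k_max: int) -> list[str]:
    """Return ids/sequences of spacers shorter than the largest requested k.

    Such spacers contain no k_max-mer and count as non-matching at that k;
    they are reported, never silently dropped.
    """
    return [sp.spacer_id or sp.seq for sp in spacers if len(sp) < k_max]


def dedup_spacers(spacers: Sequence[SpacerRecord]) -> list[SpacerRecord]:
    """Collapse duplicate sequences, summing redundancy counts (first wins ids)."""
    seen: dict[str, SpacerRecord] = {}
    for sp in spacers:
        if sp.seq in seen:
            seen[sp.seq].count += sp.count
        else:
            seen[sp.seq] = SpacerRecord(
                sp.seq, sp.genome_id, sp.array_id, sp.count, sp.spacer_id, sp.source
            )
    return list(seen.values())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_fasta(path: str | Path) -> list[NucSequence]:
    """Load a multi-record FASTA; sequences normalized to uppercase.

    Duplicate ids and non-ACGTN characters are rejected with the offending
    record named.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if first and not first.startswith(">"):
            raise FastaParseError(f"{path}: line 1: expected '>' header, got {first[:30]!r}")
    records: list[NucSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(NucSequence(rec.id, str(rec.seq)))
    return records


def write_fasta(path: str | Path, records: Iterable[NucSequence],
                descriptions: dict[str, str] | None = None) -> None:
    recs = [
        SeqRecord(Seq(r.seq), id=r.id,
                  description=(descriptions or {}).get(r.id, ""))
        for r in records
    ]
    SeqIO.write(recs, str(path), "fasta")


def load_intervals(path: str | Path) -> list[Interval]:
    """Load tab-separated (seq_id, start, end) intervals, merged per seq_id."""
    path = Path(path)
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise IntervalFormatError(f"{path}: line {lineno}: expected 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise IntervalFormatError(f"{path}: line {lineno}: {exc}") from exc
            try:
                out.append(Interval(parts[0], start, end))
            except IntervalFormatError as exc:
                raise IntervalFormatError(f"{path}: line {lineno}: {exc}") from exc
    return merge_intervals(out)


def write_intervals(path: str | Path, intervals: Iterable[Interval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\n")


def load_spacers_fasta(path: str | Path, genome_id: str = "") -> list[SpacerRecord]:
    return [
        SpacerRecord(rec.seq, genome_id=genome_id, spacer_id=rec.id)
        for rec in load_fasta(path)
    ]


def load_spacer_counts(path: str | Path, genome_id: str = "") -> list[SpacerRecord]:
    """Load a tab-separated (sequence, count) table of redundant spacers."""
    path = Path(path)
    out: list[SpacerRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise IntervalFormatError(f"{path}: line {lineno}: expected 2 columns")
            out.append(
                SpacerRecord(parts[0], genome_id=genome_id, count=int(parts[1]),
                             spacer_id=f"sp{lineno}")
            )
    return out


def write_spacers_fasta(path: str | Path, spacers: Sequence[SpacerRecord],
                        provenance: str = "") -> None:
    """Write spacers as FASTA with source provenance in the description."""
    with open(path, "w") as fh:
        for i, sp in enumerate(spacers):
            name = sp.spacer_id or f"spacer{i}"
            desc_parts = []
            if sp.genome_id:
                desc_parts.append(f"genome={sp.genome_id}")
            if sp.source is not None:
                desc_parts.append(
                    f"source={sp.source[0]}:{sp.source[1]}:{sp.source[2]}")
            if sp.count != 1:
                desc_parts.append(f"count={sp.count}")
            if provenance:
                desc_parts.append(provenance)
            desc = (" " + " ".join(desc_parts)) if desc_parts else ""
            fh.write(f">{name}{desc}\n{sp.seq}\n")


# ---------------------------------------------------------------------------
# masking
# ---------------------------------------------------------------------------

def masked_positions(genome: GenomeWithArrays) -> dict[str, np.ndarray]:
    """Per-sequence boolean mask of array positions (True = masked).

    A k-mer occurrence is masked iff its span overlaps at least one True
    position.
    """
    masks = {s.id: np.zeros(len(s), dtype=bool) for s in genome.sequences}
    for iv in genome.arrays:
        if iv.seq_id not in masks:
            raise IntervalFormatError(
                f"interval references unknown sequence {iv.seq_id!r}")
        masks[iv.seq_id][iv.start:iv.end] = True
    return masks
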