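"""Null spacer sets: genome-sampled mock spacers and scrambled spacers.

Mock spacers are length-matched verbatim fragments of the host genome drawn
uniformly from all windows lying entirely outside annotated CRISPR arrays
(and containing no N). Scrambled spacers are per-spacer uniform permutations
of the real spacers' nucleotides, preserving composition exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seqs import GenomeWithArrays, SpacerRecord, masked_positions


class SamplingExhaustedError(RuntimeError):
    """No eligible window exists for a requested mock length."""


@dataclass(frozen=True)
class ControlSpec:
    """Provenance of a control set; the seed is recorded in all outputs."""

    kind: str  # "mock" | "scrambled"
    seed: int
    max_rejections: int = 1000

    def __post_init__(self) -> None:
        if self.kind not in ("mock", "scrambled"):
            raise ValueError(f"unknown control kind {self.kind!r}")
        if self.max_rejections <= 0:
            raise ValueError("max_rejections must be > 0")


def _eligible_windows(genome: GenomeWithArrays, length: int
                      ) -> list[tuple[str, np.ndarray]]:
    """Per-sequence eligible start offsets for windows of the given length.

    Eligible = fully inside the sequence, no N, no overlap with any array
    interval. Enumerated exhaustively so sampling is exactly uniform over
    (sequence, offset) pairs.
    """
    masks = masked_positions(genome)
    out: list[tuple[str, np.ndarray]] = []
    for s in genome.sequences:
        n = len(s) - length + 1
        if n <= 0:
            out.append((s.id, np.empty(0, dtype=np.int64)))
            continue
        bad = np.frombuffer(s.seq.encode("ascii"), dtype=np.uint8) == ord("N")
        blocked = (bad | masks[s.id]).astype(np.int64)
        cs = np.concatenate(([0], np.cumsum(blocked)))
        ok = (cs[length:] - cs[:-length]) == 0
        out.append((s.id, np.flatnonzero(ok).astype(np.int64)))
    return out


def sample_mock_spacers(
    genome: GenomeWithArrays,
    lengths: Sequence[int],
    seed: int,
) -> list[SpacerRecord]:
    """One mock spacer per requested length, in order.

    Each mock is a forward-strand verbatim substring of a host sequence,
    drawn uniformly over all eligible windows of that length, independently
    (with replacement) per mock. Raises SamplingExhaustedError naming the
    length when no eligible window exists.
    """
    rng = np.random.default_rng(seed)
    cache: dict[int, tuple[list[tuple[str, np.ndarray]], np.ndarray, int]] = {}
    mocks: list[SpacerRecord] = []
    for i, L in enumerate(lengths):
        if L <= 0:
            raise ValueError(f"mock length must be positive, got {L}")
        if L not in cache:
            wins = _eligible_windows(genome, L)
            sizes = np.array([w[1].size for w in wins], dtype=np.int64)
            total = int(sizes.sum())
            cache[L] = (wins, np.cumsum(sizes), total)
        wins, cum, total = cache[L]
        if total == 0:
            raise SamplingExhaustedError(
                f"no eligible window of length {L} in genome "
                f"{genome.genome_id!r} (outside arrays, N-free)"
            )
        r = int(rng.integers(total))
        si = int(np.searchsorted(cum, r, side="right"))
        seq_id, offsets = wins[si]
        prev = int(cum[si - 1]) if si > 0 else 0
        start = int(offsets[r - prev])
        seq = genome.sequence(seq_id).seq[start:start + L]
        mocks.append(
            SpacerRecord(
                seq,
                genome_id=genome.genome_id,
                spacer_id=f"mock{i}",
                source=(seq_id, start, "+"),
            )
        )
    return mocks


def mock_spacers_for(
    genome: GenomeWithArrays, spacers: Sequence[SpacerRecord], seed: int,
) -> list[SpacerRecord]:
    """Length-matched mock set: one mock per real spacer, same lengths."""
    return sample_mock_spacers(genome, [len(sp) for sp in spacers], seed)


def scramble_spacers(
    spacers: Sequence[SpacerRecord], seed: int,
) -> list[SpacerRecord]:
    """Independent uniform permutation of each spacer's characters.

    Per-spacer length and nucleotide multiset are conserved exactly; counts
    and identity metadata are carried over.
    """
    if not spacers:
        raise ValueError("spacer list must be non-empty")
    rng = np.random.default_rng(seed)
    out: list[SpacerRecord] = []
    for i, sp in enumerate(spacers):
        chars = np.frombuffer(sp.seq.encode("ascii"), dtype=np.uint8)
        shuf = chars[rng.permutation(chars.size)]
        out.append(
            SpacerRecord(
                shuf.tobytes().decode("ascii"),
                genome_id=sp.genome_id,
                array_id=sp.array_id,
                count=sp.count,
                spacer_id=f"scr{i}",
            )
        )
    return out
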