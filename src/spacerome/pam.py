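"""PAM tabulation for experimentally acquired spacers.

For each spacer the first perfect full-length match in a reference (phage or
host genome) is located and the 3-nt protospacer-adjacent motif immediately
5' of the protospacer, on the protospacer-containing strand, is extracted.
Counts are weighted by spacer redundancy. The motif window is configurable
(default start -3 relative to the protospacer start, width 3, the standard
I-E AAG convention; -2 gives the variant that includes the protospacer's
first position).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .seqs import NucSequence, SpacerRecord, reverse_complement

PAM_WIDTH = 3


@dataclass
class PamTable:
    counts: dict[str, float] = field(default_factory=dict)
    window_start: int = -PAM_WIDTH
    n_matched: float = 0.0  # weighted spacers with a located, context-ok match

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))

    @property
    def top_pam(self) -> str | None:
        if not self.counts:
            return None
        return max(sorted(self.counts), key=lambda p: self.counts[p])

    @property
    def top_fraction(self) -> float:
        t = self.total
        return self.counts[self.top_pam] / t if t > 0 else 0.0


def first_perfect_match(
    spacer: SpacerRecord | str, reference: Sequence[NucSequence],
) -> tuple[str, int, str] | None:
    """First perfect full-length match of the spacer in the reference.

    Sequences are scanned in input order; within a sequence the smallest
    forward-strand start is preferred, falling back to the smallest
    reverse-complement start. Returns (seq_id, start, strand) or None.
    """
    seq = spacer.seq if isinstance(spacer, SpacerRecord) else spacer
    rc = reverse_complement(seq)
    for rec in reference:
        pos = rec.seq.find(seq)
        if pos >= 0:
            return (rec.id, pos, "+")
        pos = rec.seq.find(rc)
        if pos >= 0:
            return (rec.id, pos, "-")
    return None


def extract_pam(
    reference: Sequence[NucSequence],
    location: tuple[str, int, str],
    spacer_length: int,
    window_start: int = -PAM_WIDTH,
) -> str | None:
    """3-nt motif at window_start relative to the protospacer start, on the
    protospacer strand.

    For a forward hit at p the motif occupies genome positions
    [p + window_start, p + window_start + 3). For a reverse hit the
    protospacer strand is the reverse complement, so the motif is the
    reverse complement of the genome slice mirrored about the match end.
    Returns None when the window falls outside the sequence or contains N.
    """
    seq_id, start, strand = location
    rec = next(r for r in reference if r.id == seq_id)
    if strand == "+":
        lo = start + window_start
        hi = lo + PAM_WIDTH
        if lo < 0 or hi > len(rec):
            return None
        pam = rec.seq[lo:hi]
    else:
        end = start + spacer_length  # exclusive, genome coordinates
        # position j on the protospacer strand (j = window_start .. ) maps to
        # genome position end - 1 - j; the motif genome slice is
        # [end - window_start - 3, end - window_start), reverse-complemented.
        lo = end - window_start - PAM_WIDTH
        hi = end - window_start
        if lo < 0 or hi > len(rec):
            return None
        pam = reverse_complement(rec.seq[lo:hi])
    if "N" in pam:
        return None
    return pam


def pam_table(
    spacers: Sequence[SpacerRecord],
    reference: Sequence[NucSequence],
    window_start: int = -PAM_WIDTH,
    weighted: bool = True,
) -> PamTable:
    """Count-weighted PAM tabulation over the first perfect match of each
    spacer; spacers without a match or without sufficient flanking context
    are excluded from the total."""
    if not spacers:
        raise ValueError("spacer set must be non-empty")
    table = PamTable(window_start=window_start)
    for sp in spacers:
        loc = first_perfect_match(sp, reference)
        if loc is None:
            continue
        pam = extract_pam(reference, loc, len(sp), window_start)
        if pam is None:
            continue
        w = float(sp.count if weighted else 1)
        table.counts[pam] = table.counts.get(pam, 0.0) + w
        table.n_matched += w
    return table
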