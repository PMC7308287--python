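"""k-mer enumeration, reverse-complement-aware exact search, and the
pseudo-count match-fraction statistic swept over k.

A spacer "matches" a target set at a given k iff at least one of its k-mers
(step-1 sliding windows, deduplicated) or their reverse complements occurs
verbatim in any target sequence at a position whose span does not overlap a
masked position. Match rates are reported with pseudo-counts as
``(m + 1) / (N + 2)`` where ``m`` of ``N`` spacers have at least one match;
with redundant datasets each spacer contributes its count to both m and N.

The vectorised search packs windows into 2-bit integer codes; a brute-force
string scan with identical semantics (`find_occurrences_naive`) serves as an
independent oracle in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .seqs import (
    GenomeWithArrays,
    NucSequence,
    SpacerRecord,
    encode,
    masked_positions,
    reverse_complement,
)

MAX_K = 31  # 2 bits per base in a signed 64-bit code

DEFAULT_K_RANGE = tuple(range(8, 23))


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class KmerQuery:
    """Non-redundant forward-orientation k-mers generated from one spacer."""

    k: int
    kmers: frozenset[str]


@dataclass
class TargetSet:
    """Named collection of target sequences with an optional position mask."""

    target_set_id: str
    sequences: list[NucSequence]
    mask: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_genome(cls, genome: GenomeWithArrays) -> "TargetSet":
        """Self-search target: the host genome with all arrays masked."""
        return cls(genome.genome_id, genome.sequences, masked_positions(genome))

    @classmethod
    def from_sequences(cls, target_set_id: str,
                       sequences: Iterable[NucSequence]) -> "TargetSet":
        return cls(target_set_id, list(sequences))


@dataclass
class MatchCurve:
    """Per-k match counts and pseudo-count fractions for one pairing."""

    spacer_set_id: str
    target_set_id: str
    k_values: tuple[int, ...]
    m_per_k: np.ndarray          # weighted counts of spacers with >=1 match
    N: float                     # weighted total spacers (constant across k)
    weighted: bool = False
    indicators: np.ndarray | None = None  # (n_unique_spacers, n_k) bool cache
    counts: np.ndarray | None = None      # per-spacer redundancy weights

    @property
    def fraction_per_k(self) -> np.ndarray:
        return (self.m_per_k + 1.0) / (self.N + 2.0)

    def validate(self) -> None:
        if np.any(np.diff(self.m_per_k) > 0):
            raise AssertionError(
                f"m(k) must be non-increasing in k; got {self.m_per_k.tolist()} "
                f"for {self.spacer_set_id} vs {self.target_set_id}"
            )


def _check_k(k: int) -> None:
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise ParameterError(f"k must be a positive integer, got {k!r}")
    if k > MAX_K:
        raise ParameterError(f"k={k} exceeds supported maximum {MAX_K}")


def enumerate_kmers(spacer: SpacerRecord | str, k: int) -> KmerQuery:
    """All step-1 windows of length k, deduplicated; empty if spacer < k.

    Windows containing N are omitted (never generated as queries).
    """
    _check_k(k)
    seq = spacer.seq if isinstance(spacer, SpacerRecord) else spacer
    kmers = {
        seq[i:i + k]
        for i in range(len(seq) - k + 1)
        if "N" not in seq[i:i + k]
    }
    return KmerQuery(k, frozenset(kmers))


def encode_kmers(kmers: Iterable[str]) -> np.ndarray:
    """Pack k-mers over {A,C,G,T} into sorted unique int64 codes."""
    codes = []
    for km in kmers:
        c = 0
        for v in encode(km):
            if v > 3:
                raise ParameterError(f"k-mer {km!r} contains non-ACGT base")
            c = (c << 2) | int(v)
        codes.append(c)
    return np.unique(np.asarray(codes, dtype=np.int64))


def window_codes(seq: NucSequence, k: int,
                 mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """2-bit packed codes for every window of length k, plus validity flags.

    A window is invalid if it contains N or overlaps a masked position.
    """
    _check_k(k)
    a = encode(seq.seq)
    L = a.size
    n = L - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    ok = a <= 3
    b = np.where(ok, a, 0).astype(np.int64)
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes = (codes << 2) | b[j:j + n]
    # window valid iff all k bases are ACGT
    bad = (~ok).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0
    if mask is not None:
        mk = np.asarray(mask, dtype=bool).astype(np.int64)
        cm = np.concatenate(([0], np.cumsum(mk)))
        valid &= (cm[k:] - cm[:-k]) == 0
    return codes, valid


def target_code_table(targets: TargetSet, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Sorted unique valid window codes across all target sequences, with counts."""
    parts = []
    for s in targets.sequences:
        codes, valid = window_codes(s, k, targets.mask.get(s.id))
        if codes.size:
            parts.append(codes[valid])
    if not parts:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    allc = np.concatenate(parts)
    return np.unique(allc, return_counts=True)


def _lookup_counts(table: tuple[np.ndarray, np.ndarray],
                   codes: np.ndarray) -> np.ndarray:
    """Occurrence counts in the target table for each query code (0 if absent)."""
    uniq, cnt = table
    if uniq.size == 0 or codes.size == 0:
        return np.zeros(codes.size, dtype=np.int64)
    idx = np.searchsorted(uniq, codes)
    idx = np.clip(idx, 0, uniq.size - 1)
    hit = uniq[idx] == codes
    return np.where(hit, cnt[idx], 0)


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement 2-bit packed k-mer codes arithmetically."""
    rc = np.zeros_like(codes)
    c = codes.copy()
    for _ in range(k):
        rc = (rc << 2) | (3 - (c & 3))
        c >>= 2
    return rc


def _spacer_code_sets(spacers: Sequence[SpacerRecord], k: int) -> list[np.ndarray]:
    """Per-spacer deduplicated codes of forward k-mers and their revcomps.

    Spacers of equal length are batched into one matrix so the 2-bit packing
    is vectorised across the whole set.
    """
    sets: list[np.ndarray | None] = [None] * len(spacers)
    empty = np.empty(0, dtype=np.int64)
    by_len: dict[int, list[int]] = {}
    for i, sp in enumerate(spacers):
        by_len.setdefault(len(sp), []).append(i)
    for L, idxs in by_len.items():
        n_win = L - k + 1
        if n_win <= 0:
            for i in idxs:
                sets[i] = empty
            continue
        mat = np.stack([encode(spacers[i].seq) for i in idxs]).astype(np.int64)
        codes = np.zeros((len(idxs), n_win), dtype=np.int64)
        for j in range(k):
            codes = (codes << 2) | mat[:, j:j + n_win]
        both = np.concatenate([codes, revcomp_codes(codes, k)], axis=1)
        for row, i in enumerate(idxs):
            sets[i] = np.unique(both[row])
    return sets  # type: ignore[return-value]


def _own_window_hits(spacer: SpacerRecord, targets: TargetSet, k: int,
                     code_set: np.ndarray) -> int:
    """Count valid target windows overlapping the spacer's own source window
    whose code belongs to the spacer's query set."""
    if spacer.source is None:
        return 0
    seq_id, start, _strand = spacer.source
    try:
        seq = next(s for s in targets.sequences if s.id == seq_id)
    except StopIteration:
        return 0
    L = len(spacer)
    lo = max(0, start - k + 1)
    hi = min(len(seq), start + L + k - 1)  # windows starting in [lo, start+L-1]
    sub = NucSequence("_", seq.seq[lo:hi])
    m = targets.mask.get(seq_id)
    codes, valid = window_codes(sub, k, None if m is None else m[lo:hi])
    if codes.size == 0:
        return 0
    n_keep = min(codes.size, start + L - 1 - lo + 1)
    codes, valid = codes[:n_keep], valid[:n_keep]
    member = np.isin(codes, code_set)
    return int(np.sum(member & valid))


def match_indicators(
    spacers: Sequence[SpacerRecord],
    targets: TargetSet,
    k_values: Sequence[int] = DEFAULT_K_RANGE,
    exclude_source: bool = False,
) -> np.ndarray:
    """Boolean (n_spacers, n_k) matrix: spacer i has >=1 match at k_values[j].

    With ``exclude_source=True`` occurrences whose span overlaps a spacer's
    own recorded source window are suppressed (used for mock spacers in the
    self search, where the sampled window itself is a trivial hit).
    """
    if len(k_values) == 0:
        raise ParameterError("k_values must be non-empty")
    if list(k_values) != sorted(set(int(k) for k in k_values)):
        raise ParameterError("k_values must be strictly increasing")
    out = np.zeros((len(spacers), len(k_values)), dtype=bool)
    for j, k in enumerate(k_values):
        table = target_code_table(targets, k)
        code_sets = _spacer_code_sets(spacers, k)
        sizes = np.array([cs.size for cs in code_sets], dtype=np.int64)
        if sizes.sum() == 0:
            continue
        flat = np.concatenate([cs for cs in code_sets if cs.size])
        owner = np.repeat(np.arange(len(spacers)), sizes)
        hits = _lookup_counts(table, flat)
        totals = np.bincount(owner, weights=hits, minlength=len(spacers))
        out[:, j] = totals > 0
        if exclude_source:
            for i in np.flatnonzero(out[:, j]):
                if spacers[i].source is None:
                    continue
                own = _own_window_hits(spacers[i], targets, k, code_sets[i])
                out[i, j] = totals[i] > own
    return out


def spacer_has_match(spacer: SpacerRecord, k: int, targets: TargetSet) -> bool:
    """True iff any k-mer of the spacer (or its revcomp) occurs unmasked."""
    return bool(match_indicators([spacer], targets, [k])[0, 0])


def match_fraction(m: int, N: int) -> Fraction:
    """Pseudo-count match rate (m+1)/(N+2), exact."""
    if m < 0 or N < 0 or m > N:
        raise ParameterError(f"need 0 <= m <= N, got m={m}, N={N}")
    return Fraction(m + 1, N + 2)


def match_curve(
    spacers: Sequence[SpacerRecord],
    targets: TargetSet,
    k_values: Sequence[int] = DEFAULT_K_RANGE,
    weighted: bool = False,
    exclude_source: bool = False,
    spacer_set_id: str = "spacers",
) -> MatchCurve:
    """Per-k weighted match counts and pseudo-count fractions.

    Spacers shorter than k contribute no k-mers and count as non-matching at
    that k; N is constant across the sweep.
    """
    ind = match_indicators(spacers, targets, k_values, exclude_source)
    counts = np.array(
        [sp.count if weighted else 1 for sp in spacers], dtype=np.int64)
    m_per_k = (ind * counts[:, None]).sum(axis=0)
    curve = MatchCurve(
        spacer_set_id=spacer_set_id,
        target_set_id=targets.target_set_id,
        k_values=tuple(int(k) for k in k_values),
        m_per_k=m_per_k,
        N=float(counts.sum()),
        weighted=weighted,
        indicators=ind,
        counts=counts,
    )
    curve.validate()
    return curve


def weighted_match_fraction(
    spacers: Sequence[SpacerRecord], k: int, targets: TargetSet,
) -> Fraction:
    """Count-weighted pseudo-count fraction at a single k."""
    ind = match_indicators(spacers, targets, [k])[:, 0]
    m = sum(sp.count for sp, hit in zip(spacers, ind) if hit)
    N = sum(sp.count for sp in spacers)
    return Fraction(m + 1, N + 2)


# ---------------------------------------------------------------------------
# positional search (used by the PAM stage and as the contract surface the
# brute-force oracle checks)
# ---------------------------------------------------------------------------

def find_occurrences(
    query: KmerQuery, targets: TargetSet,
) -> list[tuple[str, int, str]]:
    """Every unmasked position where a query k-mer (strand '+') or its
    reverse complement (strand '-') occurs in a target sequence.

    A palindromic/self-complementary hit is reported on both strands. Results
    are ordered by target input order, then position, then strand ('+' first).
    """
    if not query.kmers:
        return []
    fwd = encode_kmers(query.kmers)
    rev = encode_kmers(reverse_complement(km) for km in query.kmers)
    out: list[tuple[str, int, str]] = []
    for s in targets.sequences:
        codes, valid = window_codes(s, query.k, targets.mask.get(s.id))
        if codes.size == 0:
            continue
        fhit = np.flatnonzero(valid & np.isin(codes, fwd))
        rhit = np.flatnonzero(valid & np.isin(codes, rev))
        merged = sorted(
            [(int(p), "+") for p in fhit] + [(int(p), "-") for p in rhit])
        out.extend((s.id, p, st) for p, st in merged)
    return out


def find_occurrences_naive(
    query: KmerQuery, targets: TargetSet,
) -> list[tuple[str, int, str]]:
    """Brute-force substring scan with identical semantics; oracle for tests."""
    if not query.kmers:
        return []
    k = query.k
    rc = {reverse_complement(km) for km in query.kmers}
    out: list[tuple[str, int, str]] = []
    for s in targets.sequences:
        mask = targets.mask.get(s.id)
        per_seq: list[tuple[int, str]] = []
        for pos in range(len(s.seq) - k + 1):
            window = s.seq[pos:pos + k]
            if "N" in window:
                continue
            if mask is not None and bool(mask[pos:pos + k].any()):
                continue
            if window in query.kmers:
                per_seq.append((pos, "+"))
            if window in rc:
                per_seq.append((pos, "-"))
        out.extend((s.id, p, st) for p, st in sorted(per_seq))
    return out
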