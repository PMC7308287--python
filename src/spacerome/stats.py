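"""Real-vs-control comparison: enrichment/depletion ratios across k,
bootstrap ranges of the match fraction, and the range-non-overlap rule.

The ratio of the pseudo-count match fractions (real / control) quantifies
relative enrichment (>1) or depletion (<1) of matches. Uncertainty is
assessed by B-fold bootstrap resampling of the spacer set, recording the
min–max range of the resampled fractions; non-overlap of two ranges is the
significance call. Resampling reuses cached per-spacer match indicators, so
no re-search is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .kmers import MatchCurve

DEFAULT_B = 1000


class AlignmentError(ValueError):
    """Curves or ranges computed on different k grids cannot be compared."""


@dataclass
class RatioCurve:
    numerator_id: str
    denominator_id: str
    k_values: tuple[int, ...]
    ratio_per_k: np.ndarray


@dataclass
class BootstrapRange:
    """Min–max range of B resampled pseudo-count fractions at one k.

    ``plo``/``phi`` additionally record the 2.5–97.5 percentile band.
    """

    k: int
    B: int
    lo: float
    hi: float
    plo: float
    phi: float
    seed: int

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise AssertionError("bootstrap range has lo > hi")


def ratio_curve(real: MatchCurve, control: MatchCurve) -> RatioCurve:
    """Elementwise real/control pseudo-count fraction ratio.

    Pseudo-counts guarantee a finite positive ratio at every k.
    """
    if real.k_values != control.k_values:
        raise AlignmentError(
            f"k grids differ: {real.k_values} vs {control.k_values}")
    return RatioCurve(
        numerator_id=f"{real.spacer_set_id}|{real.target_set_id}",
        denominator_id=f"{control.spacer_set_id}|{control.target_set_id}",
        k_values=real.k_values,
        ratio_per_k=real.fraction_per_k / control.fraction_per_k,
    )


def bootstrap_fractions(
    indicators: np.ndarray,
    B: int,
    seed: int,
    counts: np.ndarray | None = None,
) -> np.ndarray:
    """B resampled pseudo-count fractions from a match-indicator vector.

    Unweighted: N spacers are resampled with replacement per replicate.
    Weighted: the redundant dataset of size N_total = sum(counts) is
    resampled, drawing unique spacers with probability proportional to their
    counts, matching the weighted fraction definition.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    ind = np.asarray(indicators, dtype=bool)
    n = ind.size
    if n == 0:
        raise ValueError("spacer set must be non-empty")
    rng = np.random.default_rng(seed)
    if counts is None or np.all(np.asarray(counts) == 1):
        # sort first: the resampling distribution depends only on the
        # indicator multiset, and sorting makes that exact per seed
        ind = np.sort(ind)
        idx = rng.integers(0, n, size=(B, n))
        m = ind[idx].sum(axis=1)
        N = n
    else:
        counts = np.asarray(counts, dtype=np.int64)
        order = np.lexsort((counts, ind))
        ind, counts = ind[order], counts[order]
        N = int(counts.sum())
        p = counts / N
        draws = rng.choice(n, size=(B, N), p=p)
        m = ind[draws].sum(axis=1)
    return (m + 1.0) / (N + 2.0)


def bootstrap_fraction_range(
    indicators: np.ndarray,
    k: int,
    B: int = DEFAULT_B,
    seed: int = 0,
    counts: np.ndarray | None = None,
) -> BootstrapRange:
    """Min–max (and 2.5–97.5 percentile) range of B resampled fractions."""
    fr = bootstrap_fractions(indicators, B, seed, counts)
    plo, phi = np.percentile(fr, [2.5, 97.5])
    return BootstrapRange(
        k=int(k), B=int(B),
        lo=float(fr.min()), hi=float(fr.max()),
        plo=float(plo), phi=float(phi),
        seed=int(seed),
    )


def curve_bootstrap_ranges(
    curve: MatchCurve, B: int = DEFAULT_B, seed: int = 0,
) -> list[BootstrapRange]:
    """Bootstrap range at every k of a MatchCurve (cached indicators)."""
    if curve.indicators is None:
        raise ValueError("curve carries no cached indicators")
    counts = curve.counts if curve.weighted else None
    return [
        bootstrap_fraction_range(
            curve.indicators[:, j], k, B, seed + j, counts)
        for j, k in enumerate(curve.k_values)
    ]


def ranges_nonoverlap(a: BootstrapRange, b: BootstrapRange) -> bool:
    """True iff the two [lo, hi] ranges are disjoint (shared endpoint counts
    as overlap; non-overlap is the strong-significance call)."""
    if a.k != b.k:
        raise AlignmentError(f"ranges at different k: {a.k} vs {b.k}")
    return a.hi < b.lo or b.hi < a.lo
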