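# Methods

## The procedure

Given a set of spacers, a host genome with annotated CRISPR-array intervals,
and a target virome, the analysis computes, for each k in a sweep (default
8–22 inclusive):

1. each spacer's non-redundant set of k-mers (step-1 sliding window;
   spacers shorter than k contribute no k-mers and count as non-matching,
   so N is constant across the sweep and per-k fractions are comparable);
2. exact occurrences of those k-mers and their reverse complements in the
   target sequences, suppressing any occurrence whose span overlaps a
   masked position (all annotated array intervals are masked in the
   self-search — any array copy of a spacer is a trivial self hit);
3. the pseudo-count match fraction (m+1)/(N+2), where m of N spacers have
   at least one surviving occurrence. With redundant (experimentally
   acquired) datasets, each unique spacer contributes its redundancy count
   to both m and N; mock sets are always counted unweighted.

Real curves are compared to two nulls. *Mock spacers* are length-matched
fragments drawn uniformly from all host windows lying fully outside array
intervals and containing no N; sampling is with replacement and exactly
uniform because the eligible windows are enumerated exhaustively rather
than rejection-sampled (a request for a length with no eligible window
fails loudly). *Scrambled spacers* are independent uniform permutations of
each real spacer. The per-k real/control fraction ratio measures enrichment
(>1) or depletion (<1). Uncertainty comes from B-fold (default 1000)
bootstrap resampling of the spacer set, reusing cached per-spacer match
indicators; the recorded range is the min–max of the B resampled fractions
(a 2.5–97.5 percentile band is kept as a secondary output), and
non-overlap of two ranges — with a shared endpoint conservatively counted
as overlap — is the strong-significance call. No analytic p-value is
printed.

### Mock self-search: own-window exclusion

A mock spacer is a verbatim substring of the host, so in the self-search it
would trivially match at its own sampled location and the mock self curve
would be identically 1. The analogue of excluding a real spacer's source
array is therefore applied: occurrences whose span overlaps the mock's own
source window are suppressed (only) in the mock-vs-host comparison. What
remains measures genuine repeat structure — a mock self-matches iff its
sequence occurs somewhere else in the genome. Real spacers never have their
source windows excluded; a planted host-derived spacer legitimately
self-matches at its source.

### PAM extraction

For each (unique) spacer the first perfect full-length match is located —
sequences scanned in input order, smallest forward-strand start preferred
within a sequence, then smallest reverse-complement start — and the 3 nt
immediately 5′ of the protospacer on the protospacer-containing strand are
tabulated with redundancy weighting. The window is configurable
(`window_start`, default −3, width 3): the default is the standard
strictly-upstream convention under which the type I-E motif reads AAG;
`window_start=-2` gives the variant that includes the protospacer's first
base. Matches with fewer than 3 nt of flanking context, and spacers with no
perfect match, are excluded from the table's total.

## k-mer search implementation

Windows are packed into 2-bit integer codes (k ≤ 31), target codes are
deduplicated into a sorted table with occurrence counts, and query
membership is a vectorised binary search; reverse complements are computed
arithmetically on the codes. Windows containing N are never generated from
targets or queries, and matching is exact over {A,C,G,T} after uppercase
normalisation. The packed search is contractually equivalent to a naive
substring scan; a brute-force scanner with identical semantics ships in the
package and the test suite asserts equality on hundreds of randomized
instances, including masked and N-containing targets. Coordinates are
0-based half-open throughout; multi-replicon genomes are searched as a
collection (windows never span record boundaries).

## Synthetic scenarios

The generator plants a known truth to make every stage falsifiable:

| parameter | default | meaning |
|---|---|---|
| host_length | 2 Mb | i.i.d. host genome at the given GC (0.5) |
| n_viruses × virus_length | 10 × 50 kb | repeat-free virome, same GC |
| n_proviruses × provirus_length | 3 × 20 kb | virome segments copied into the host |
| provirus_divergence | 0.15/base | substitutions applied to the integrated copy |
| n_repeat_elements × repeat_copies × repeat_length | 0 × 3 × 2 kb | verbatim repeated elements (off by default) |
| array_length | 3 kb | reserved, masked array interval (mask carrier) |
| n_spacers, spacer length | 1000, 32 nt | spacer set size |
| f_virus / f_self / f_dark | 0.08 / 0.02 / 0.90 | origin mixture |
| mu | 0.02/base | substitution noise on virus-derived spacers |
| pam, pam_fraction | none, 1.0 | 3-mer written 5′ of virus-derived protospacers |

Virus-derived spacers are substrings of the virome mutated at rate mu
(uniform among the three alternative bases); self-derived spacers are host
substrings outside the array interval; dark spacers are i.i.d. at host GC.
Adaptation-style datasets add geometric redundancy counts with mean
1 + dispersion and require a planted PAM; planted PAM windows are spaced
≥3 nt apart so no plant overwrites another.

Proviruses are planted *diverged* (default 0.15 substitutions/base) rather
than verbatim. This is the realistic prophage regime — an integrated copy
is generally not identical to the database relative of the free phage — and
it is what gives the default scenario its intended geometry: the provirus
copies still produce a small but non-zero mock-vs-virome match rate at long
k (the provirus signature), while leaving the virus-side real/mock
enrichment large and the self-match fraction attributable to the planted
f_self. With verbatim proviruses (`provirus_divergence=0`), 60 kb of
provirus in a 2 Mb host makes ~3% of mocks match the virome at every k,
capping the attainable enrichment near 3; that setting remains available
for studying exactly that artifact. Host repeats, which drive mock
*self*-matches and hence the self-depletion geometry, are a separate knob
and default to zero because the default scenario's recovery contract
(real self fraction ≈ f_self + mock-measured excess) presumes the mock
excess applies equally to the non-self spacer population.

What the generator does not emulate: real phage genome architecture, codon
or oligonucleotide composition bias (spacers and genomes share one GC),
array contents (the array interval is an empty mask carrier), acquisition
kinetics, and partial/diverged protospacers other than i.i.d. point
substitutions. Passing recovery tests therefore demonstrates correctness of
the measurement machinery under the stated statistical model, not that any
particular biological dataset will show the same numbers.

## Numerical and reproducibility choices

- k sweep default 8–22 inclusive, overridable; k ≤ 31 (2-bit packing).
- Pseudo-count fractions are exact rationals internally (`fractions.Fraction`
  for the scalar statistic); report tables render 10 significant digits.
- All randomness flows from one master seed split deterministically per
  stage (numpy SeedSequence); identical config + seed reproduces every
  output file byte-for-byte, and generated FASTA/TSV fixtures are
  byte-stable under a fixed scenario + seed.
- Bootstrap resampling sorts the indicator vector first, making the
  resampled distribution an exact function of the indicator multiset (and
  of (counts, indicators) pairs in the weighted case, where unique spacers
  are drawn with probability proportional to count).
- Mock sampling is uniform over the exhaustively enumerated eligible
  windows; ties and degenerate inputs (fully masked genome, oversize
  length) raise named errors rather than degrading silently.
- Grouped (per-genus style) analyses pool each group's spacers over the
  shared virome; self-matches are always computed against each spacer's own
  source genome.

## Problem sizes used in the shipped analyses

The default scenario (2 Mb host, 500 kb virome, 1000 spacers) is the unit
of the recovery analyses: 20 independent seeds for origin-fraction recovery
and for the mutation-erosion sweep (mu ∈ {0, 0.02, 0.05, 0.1}), 10⁴ draws
for mock-uniformity checks, B = 2000 for bootstrap calibration against the
exact binomial, and 500 randomized instances for search-oracle equivalence.
These sizes give Monte-Carlo standard errors comfortably below the effect
sizes being checked while keeping a full run at desk scale.

## Known limitations

- Exact matching only; mismatch-tolerant protospacer discovery is upstream
  input, not recomputed.
- k > 31 would require a different packing; actual spacers and the default
  sweep are far below this.
- The weighted bootstrap resamples the redundant dataset at fixed total
  size; alternative schemes (resampling unique spacers unweighted) are not
  exposed.
- PAM tabulation uses each spacer's *first* perfect match; a spacer
  occurring at several loci with different flanks is attributed to one
  locus by the documented deterministic tie-break.
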