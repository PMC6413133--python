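# Methods

This note documents the models, conventions and numerical choices behind
`polyasig`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinate convention

All analyses run on 400-nt windows spanning 300 nt upstream and 100 nt
downstream of a poly(A) site. The cleavage base is position −1; there is no
position 0; +1 is the first downstream base. Array index *i* maps to
position *i* − 300 for *i* < 300 and *i* − 299 otherwise, so index 299 ↔ −1
and index 300 ↔ +1. On the minus strand the window is the reverse
complement of genomic `[coord − 100, coord + 299]` (1-based), so the
returned sequence always reads 5′→3′ of the transcript with the cleavage
base at −1. Windows that would run past a contig end are dropped and
counted, never N-padded: every per-transcript percentage downstream divides
by a set of complete 400-nt windows. Sequences are DNA (T) internally;
motifs and reports use the RNA alphabet (U), as poly(A) signals are
conventionally written. Any IUPAC code outside ACGT is read as N; N never
matches a motif, never trains the background, and is excluded from profile
and dinucleotide denominators.

## Internal-priming filter

A window is an internal-priming candidate when the 20 bases at −10..+10
contain a run of ≥ 6 consecutive A, or when any of the eleven 10-nt
sub-windows contains ≥ 7 A. Both rules are scoped to −10..+10 only, the
A-run may straddle the cleavage site, and N counts as non-A (conservative
retention). Flagging is monotone in A-content and filtering is idempotent;
both properties are tested. Duplicate sites (same contig, coordinate,
strand) are collapsed before extraction with summed EST support, and the
filter report assigns every input site exactly one fate so counts conserve.

## Counting modes

`overlap` counts every match start. `gap` scans left→right and, after
accepting a match at start *p*, accepts no start before *p* + gap + 1; the
default gap = k − 1 yields the greedy non-overlapping count (verified
exhaustively against a regex oracle over all ≤12-nt two-letter sequences).
gap = 0 reproduces `overlap`. `once` keeps at most one match per window:
the one whose start position is closest to the poly(A) site, with a tie
across the site (|−p| = |+p|) broken upstream — ties at a single offset are
impossible since starts are distinct. A match belongs to a region only if
the whole k-mer lies inside it, making region counts additive over disjoint
regions. Ranked tables report *per-transcript frequency*: the percentage of
windows with ≥ 1 in-region hit, counted in gap mode by default (the mode is
selectable); ranking ties break by total occurrences, then lexicographic
order, so output is fully deterministic. Exhaustive scanning enumerates
observed k-mers via hash counting, which is exact and linear in input size.

## Background model and Z-scores

Over-representation of word *w* (length *k*) in a region is scored as

    z = (O − E) / sd,   E = T·P(w),   sd = √(T·P(w)·(1 − P(w)))

with *O* the overlap-mode count (the expectation covers *all* start
positions, so a non-overlapping observed count would bias z downward),
*T* = Σ windows (region length − k + 1), and P(w) the probability of *w*
under an order-*m* Markov chain fitted by maximum likelihood to the same
region's sequences, with an add-0.25 pseudocount per cell (initial
distribution over all 4^m contexts; every transition row sums to 1, so
word probabilities of all 4^k words sum to exactly 1 — tested
exhaustively). The binomial variance ignores word self-overlap
autocorrelation; exact overlap-corrected variances are out of scope and the
binomial form is the standard default for this family of statistics.
Order and cutoff follow motif length: k ∈ {3,4} → order 1, z ≥ 5;
k ∈ {5..8} → order 3, z ≥ 3. The background trains on the scanned region by
default (selectable).

A practical caveat, verified on generator output: an order-3 background
fitted to sequences containing a strongly planted pentamer absorbs much of
that word's internal correlation into its transition rows. The planted
word's z remains clearly above cutoff, but nearby rare words (sharing
trigrams with the plant) can reach comparable or higher z. Rankings of
*significance* under high-order backgrounds therefore should not be read as
rankings of *importance*; the frequency table is the primary ranking and
the z-score a significance gate. The parameter-recovery test accordingly
asserts top-1 by z under an order-1 background and top-1 by frequency plus
z > cutoff under the length policy.

## Profiles and region inference

Single-nucleotide profiles are per-position empirical base frequencies
(4 × 400, A/C/G/U). Region inference proceeds as:

* **NUE**: start = first A/U crossing found in −45..−20, end = last in
  −20..−5 (fallbacks −30 / −10). A crossing is reported at position *p*
  when fA − fU is exactly 0 at *p* or changes sign between *p* and *p*+1.
  Detection runs on a width-5 moving-average smoothed profile and requires
  the difference to reach ±0.05 within 3 positions of the candidate —
  without this magnitude confirmation, a flat profile's sampling noise
  produces sign flips everywhere and would defeat the documented fallbacks.
  When a motif positional distribution is supplied, the NUE widens to cover
  ≥ 90% of its occurrences (central-quantile bounds).
* **FUE**: from the 5′-most run of ≥ 20 consecutive positions where G or U
  exceeds every other base by ≥ 0.05 (fallback −200) to NUE start − 1.
  Dominance is judged on the *raw* profile: smoothing bleeds composition
  across a sharp boundary and would shift the detected start 1–2 nt 5′-ward
  of the true composition change.
* **CE**: fixed at −10..+10.

All thresholds (smoothing width, confirmation magnitude, dominance margin
and run length, search windows) are keyword arguments with the defaults
above. Manual regions are first-class (`manual_regions`), and inference
refuses profiles built from fewer than 50 windows. The cleavage
dinucleotide table tallies (−2, −1) per window with aggregates YA = UA + CA
and BA = YA + GA, so BA − YA = f(GA) identically.

## Variant groups, PFM and PSSM

The single-nucleotide variant neighborhood of a canonical signal has
exactly 3k members. A variant joins the group when it appears within the
top-100 ranked same-length motifs (the top 50 typically misses
low-frequency variants); the canonical is always a member, at frequency 0
with a warning when unobserved. The combined frequency is the plain sum of
member per-transcript frequencies — a window carrying two members counts in
both, making this a signal-mass tabulation rather than a detection rate.
The group PFM weights each member's bases by its frequency percentage
(columns sum to 1); the PSSM is log2((PFM + 0.01 pseudocount,
renormalized) / background) with a uniform default background, scored
additively over positions. Canonical-signal comparison coordinates are
plain region scans with fixed regions: UGUAA in −80..−15 and AAUAAA in
−50..−15.

## Synthetic data generator

The generator emulates the architecture the analysis assumes and nothing
more. Defaults (all overridable through `SimConfig`):

| parameter | default | rationale |
|---|---|---|
| segment compositions | uniform −300..−181; U-rich (A .15, C .20, G .20, U .45) −180..−32; A-rich (mirrored) −31..−12; U-rich −11..+10; uniform +11..+100 | a U-dominant FUE from −180 and A/U crossings at −32 and −12; the mirrored |fA − fU| margins (0.3 both sides) keep crossing positions invariant under profile smoothing |
| planted motif, π, interval | UGUAA, 0.5, fully inside −30..−15 | a strong canonical-pentamer species; planting overwrites bases (window length fixed), uniform start over feasible offsets |
| CE dinucleotide, ρ | CA, 0.7 | dominant BA-class dinucleotide at −2/−1 at a realistic aggregate frequency |
| priming decoys q | 0 | a 6-A run overwritten at a uniform feasible start inside −10..+10 when enabled |
| duplicate rate | 0 | duplicate site rows for deduplication tests |
| n_sites | 2000 | large enough for ±1-point frequency resolution and stable region inference while keeping any full run in seconds |

Windows are embedded in one contig with 100-nt flanks and spacers so
extraction never truncates; every stochastic choice flows from a single
`numpy` generator seeded by `SimConfig.seed`, giving bit-reproducible
output. `expected_frequency` returns the analytic per-window detection
probability π + (1 − π)(1 − Π(1 − P(w at start))) used as the oracle in
recovery tests; it ignores background hits inside planted windows (a
second-order undercount well within the 3-standard-error test tolerances).

What the generator does **not** emulate: EST sequencing noise, species
nucleotide-profile shapes beyond piecewise-constant compositions,
correlated positions (the background is i.i.d. per position within a
segment), alternative/clustered poly(A) sites, or minus-strand sites (the
extraction logic's strand handling is tested separately on hand-built
contigs). Passing recovery tests therefore demonstrates correctness of the
measurement machinery under the assumed architecture, not performance on
real EST-derived data.

Tests that need a clean decoy truth set (exact flag/truth agreement) lower
the CE/downstream A fraction to 0.02, since under the default composition
(A = 0.15) a thousand windows contain an expected 1–2 genuine background
A-runs that the filter would — correctly — flag.

## Problem sizes and determinism

The standard validation runs use n = 2000 windows for end-to-end recovery
and region inference, n = 1000 for decoy filtering, and n = 5000 for
variant-group frequency recovery; at these sizes every quantity under test
sits several standard errors from its decision boundary, and the whole
suite plus the acceptance script complete in well under a minute. Property
tests are derandomized; all generator use is explicitly seeded. Known
limitations: no IUPAC-degenerate motif patterns, no EM/Gibbs motif
discovery, no overlap-corrected word-count variances, no multiple-testing
correction across the 4^k motif family (reported counts are descriptive),
and no plot rendering (profiles, PFMs and PSSMs are emitted as TSV matrices
consumable by standard logo renderers).
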