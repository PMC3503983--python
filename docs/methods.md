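# Methods

This note documents the models, the default parameters, the synthetic-data
generator and the deliberate design choices behind `ltrfate`.

## The generative model

A synthetic region is a random background sequence (default GC fraction
0.43, typical of grass BAC regions) into which features are spliced:
genes (exon/intron intervals), LTR retrotransposons of configured family,
age and fate, DNA transposons, tandem-repeat arrays, and gene-movement
footprints.  Coordinates are 0-based half-open throughout; the GFF3
writers convert to the format's 1-based inclusive convention.

**Substitution process.**  Element-derived sequence (both LTR copies and
the internal region) evolves under a continuous-time Kimura two-parameter
process parameterized by the per-site per-year rate *r* (default
1.3×10⁻⁸) and the transition/transversion *rate* ratio κ (default 2).
For branch length *d* = *r*·age the per-site change probabilities are

    βt = d/(κ+2),  αt = κ·d/(κ+2)
    P(transition)       = 1/4 + 1/4·e^(−4βt) − 1/2·e^(−2(α+β)t)
    P(any transversion) = 1/2 − 1/2·e^(−4βt)

The two LTR copies evolve independently, so the expected copy-to-copy
divergence corresponds to branch length 2·*r*·age, which is exactly what
the K2P dating estimator inverts.  Indels are **not** simulated inside
elements: the dating oracle stays exact and the annotator's ungapped
alignment stages are sufficient.  This is a stated contract, not an
accident — on real data, where LTRs do accumulate indels, the annotator
is a first-pass screen whose calls a curator refines.

**What does not evolve.**  Host flanks and TSD copies are planted and left
unmutated.  TSD identity is the signal that separates intra- from
inter-element recombination in the fate taxonomy, and the generator
plants that signal directly rather than layering flank divergence on top
of it.  Consequently a passing TSD test certifies the detector, not
robustness to TSD decay in old insertions.

**Repeat maximality.**  For intact elements the generator resamples the
internal base immediately inside each LTR junction so that the aligned
columns just outside the LTR pair are guaranteed mismatches.  Without
this, the maximal exact repeat genuinely extends past the planted
annotation with probability ≈ 1/4 per boundary (a chance flank match),
and *no* detector could recover the planted boundary exactly.  The planted
repeat is thereby maximal — its true extent equals its annotation.

**Family spacing.**  Copies of one family (including the partner-family
LTR inside a recombination-complex chimera) are placed at least
`family_spacing` (default 20 kb) apart, beyond the structural search's
`max_span` (18 kb).  This makes the LTR pairing identifiable: otherwise a
5'LTR of one copy can legitimately pair with the 3'LTR of a neighboring
copy and no positional algorithm could tell the difference.  Real
high-copy regions do contain such ambiguous configurations; recovering
them is outside what the planted-truth tests certify.

**Seeding.**  One master seed; the background, each family consensus and
each planted feature draw from separate deterministic substreams, so
adding a feature never perturbs earlier ones and identical configurations
produce byte-identical output.

## Annotation

* **LTR pair search** (`find_ltr_pairs`): exact 20-mer seeding of the
  sequence against itself (forward strand only — LTR copies are
  co-oriented), ungapped X-drop extension (X = 25) along each seeded
  diagonal, then boundary trimming to the outermost run of 8 consecutive
  matches.  Bounds: LTR length 100–3000 bp, outer span 1–18 kb, identity
  ≥ 0.80 — literature-typical settings, configurable.  The terminal-run
  trim pins boundaries to solid identity; an isolated chance match beyond
  the element cannot drag the boundary outward.
* **Library matching** (`match_library`): each family consensus (LTR,
  internal, or whole element) is seeded (12-mers) and extended ungapped
  against both strands; hits need identity ≥ 0.80 and either 40 bp or 10%
  of the consensus, whichever is larger.  Hit boundaries are then
  extrapolated to the full consensus extent when at most 25 terminal
  consensus bases are unmatched — exact under substitution-only evolution
  — which recovers true element boundaries at any divergence while
  leaving genuinely truncated remnants (larger missing blocks) alone.
* **TSD detection** (`detect_tsd`): longest exact duplicated motif
  (4–20 bp) whose copies abut the element boundaries within a 2 bp
  window; ties broken by boundary proximity, then leftmost.  Element
  assembly asks for ≥ 5 bp (the canonical LTR-element TSD length): at a
  2 bp window, chance 4-mers flank roughly 3% of TSD-less elements, chance
  5-mers under 1%.
* **Assembly** (`assemble_elements`): structural pairs become element
  skeletons; hits attach to the innermost containing skeleton (so nested
  guests keep their own evidence); internal hits attach when they
  majority-overlap the inter-LTR gap; leftover hits cluster at ≤ 300 bp
  gaps into homology-only elements (solos, truncated remnants, DNA TEs).
  Structural evidence outranks homology for coordinates, except that a
  matching LTR hit refines a skeleton's boundary via consensus
  extrapolation.

## Fate classification

The cascade (first match wins) over an element's sub-features, with LTR
"full length" meaning ≥ 0.8 consensus coverage and internal presence
meaning ≥ 0.5 summed coverage:

1. two full LTRs of one family + internal → Intact LTR (with/without TSD
   by TSD presence);
2. evidence from two families → Recombination complex;
3. single full LTR, no internal evidence within 500 bp → solo
   (with/without TSD);
4. partial LTR evidence only → Truncated Solo;
5. internal + exactly one LTR → 3'/5' LTR deleted by which side is
   absent (strand-aware);
6. otherwise → partially deleted.

The thresholds (0.8 / 0.5 / 500 bp) are this package's own, exposed as
keyword arguments; the taxonomy they implement was originally applied by
manual curation, which published no numeric criteria.

The category→mechanism mapping is a fixed total function (Solo w/TSD →
UR(Intra), Solo w/o TSD → UR(Inter), Intact w/o TSD → UR(Intra),
Truncated Solo → UR(Inter) or UR(Intra)&IR, the three deletion fates →
IR, Recombination complex → UR(Inter), Intact → none).

**Tendency.**  The E/C (expansion/contraction) label is a bp balance:
E when the LTR-derived bp still present exceed the bp inferred removed
(per non-intact remnant: library-reconstructed intact length minus
observed length), C otherwise.  Published per-region tendency labels
follow no recoverable count-based formula (regions with more solos than
intact elements appear under both labels), so a transparent bp-balance
definition is used and both totals are reported so users can apply any
other rule.

## Dating

`T = K/2r` with the K2P closed form on ungapped, unambiguous columns of a
global affine alignment (match +1, mismatch −1, gap of length L costs
5 + L).  The closed form is used instead of numerical ML: it is exact,
dependency-free, and is the estimator the two-rate model implies;
differences versus an HKY-style ML fit are far below the sampling noise
at these divergences.  Saturation (1−2P−Q ≤ 0 or 1−2Q ≤ 0) raises an
explicit error rather than returning a number.  Only elements with both
LTRs are dated — solo and truncated remnants carry no two-copy clock.

## Composition and profiling

Masked-bp percentages are computed at base level with each base
attributed to the innermost (most recently inserted) element, so family
rows are conserved and class totals are exact sums of their component
rows.  Intact-element rows are informational subsets, never added into
class totals.  An explicit Unclassified-RNA row carries Class I mass of
unknown family rather than hiding it.  Rounding to two decimals happens
only in the report layer.  Gene density is kb/gene (undefined for
gene-free regions).  The chromatin indicator is purely descriptive:
heterochromatin-like when Gypsy:Copia ≥ 2 **and** gene density ≥ 20
kb/gene, euchromatin-like when both are reversed, else indeterminate.

## Movement footprints

All evidence is exact-match — a conservative reading of "identical"
signatures; every reported motif occurs verbatim at its reported
coordinates.  Defaults: capture-TSD minimum 8 bp (ordinary 4–6 bp element
TSDs must not trigger pattern A; the motivating case is 10 bp), TE–gene
adjacency gap ≤ 2 kb, shared border minimum 6 bp, tandem-flank window
500 bp with 3 bp boundary slack (an array's agreement run can extend a
few bases into the gene by chance), retrocopy length tolerance 10%.
Tandem arrays are maximal period-k self-shift agreement runs (k ≤ 10 by
default), at least 4 copies and 12 bp — the length floor exists because
short-period chance runs (homopolymers) are ubiquitous in random
sequence.  Pattern B requires user-supplied donor candidates: donors were
located by prior knowledge of paralogy, and genome-wide donor discovery
is out of scope.

## Problem sizes and verification

The test suite and the acceptance script run entirely on generated data:
ten 450 kb regions with 18 planted elements each (≥ 20 per fate) for
classification and annotator recovery; 50 intact elements per age in
{0.5, 1, 2} My for dating recovery (mean recovered age within 10%);
50 planted footprints per pattern; 100 kb seeded null backgrounds for
false-positive checks; brute-force oracles for TSD detection, tandem
arrays and alignment scores on kb-scale inputs.  These sizes give tight
binomial error bars while keeping a full run in well under a minute.

## Known limitations

* No indel evolution inside elements, no TSD/flank divergence, no nested
  same-family insertions, no strand-mixed regions in the generator — the
  recovery rates quoted are for the conditions above, not for arbitrary
  real data.
* Ungapped annotation stages will fragment hits across real indels.
* No PBS/PPT or TG…CA terminal-motif detection; no HMM/profile search.
* The chromatin label is a two-threshold heuristic, not a cytological
  claim.
* Pattern B donor discovery and Pack-MULE/CACTA terminal structure
  detection are out of scope.
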