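# Methods

## Data model and coordinate conventions

All internal intervals are 0-based half-open; VCF positions are 1-based
only at the I/O edge. Chromosome names are stored without a `chr` prefix;
readers accept both dialects. Sort order is natural (1..19 numerically,
then X, Y) then position then alt allele. Multi-allelic VCF rows are
decomposed into biallelic records before anything else: a sample carrying
`1/2` becomes het for each decomposed record, and a half-missing diploid
call collapses to missing. Alleles are trimmed to minimal representation
(shared suffix, then shared prefix, keeping the anchor base); trimming is
idempotent. Full left-alignment against the reference is not performed at
read time — the variant reader works from the VCF alone — which is
adequate here because the synthetic generator emits left-anchored minimal
indels and the filters compare sites, not haplotypes.

A strain panel assigns each strain a phenotype (prone/resistant) and a
breeding role (donor parent, recipient parent, derived, or reference
assembly). Reference-assembly strains carry no genotypes and participate
only in presence/absence segregation scoring, since an assembly provides
a single haplotype.

## Marker classification

A variant is donor-specific when the donor parent is hom-alt and the
recipient hom-ref, recipient-specific in the mirror case, and
uninformative otherwise (any het or missing parental call, or equal
parental states). Classification depends only on the two parental
genotypes. The "donor state" of a derived strain at an informative marker
is the homozygous genotype matching the donor parent (hom-alt at
donor-specific sites, hom-ref at recipient-specific ones). Het and
missing calls in a derived strain are ambiguous and skipped rather than
counted as discordant: the strains are fully inbred, so residual hets are
almost always artifacts.

## Segment calling

The caller is run/gap-based, not an HMM: at congenic marker densities
(about one informative marker per kb here) a transparent, exhaustively
checkable rule is preferable to a fitted model. An emitted segment is an
inclusion-maximal pair (i, j) of informative markers such that

1. markers i and j are donor-state in the derived strain,
2. every gap between consecutive retained markers inside [i, j] is at
   most `max_gap_bp` (default 500,000),
3. the discordant fraction over the whole run —
   recipient-state/(donor-state + recipient-state) — is at most
   `max_discordant_frac` (default 0.02), and
4. donor-state support is at least `min_markers` (default 25).

The fraction constraint applies to the run as a whole (a single interior
discordant marker in a 50-marker run gives 1/51 < 0.02 and does not split
the segment). Internally the fraction constraint becomes prefix-sum
nonnegativity under weights (f for donor-state, f−1 for recipient-state),
which yields the farthest valid end J(i) for every start by binary search
on a suffix-maximum array; pairs are then pruned to the inclusion-maximal
set. The test suite verifies exact equality with an O(n²) exhaustive
enumeration of the same four conditions on instances up to 200 markers.
Segment intervals span [first supporting marker, last supporting marker]
(half-open); Mb values are rounded to two decimals only in human-readable
output.

The mapped locus is the maximal interval contained in some segment of
every prone derived strain (ties broken leftmost; an empty intersection
returns a zero-length interval with a warning).

### Boundary accuracy is a marker-resolution statement

The detected boundary can never be closer to the true breakpoint than the
nearest informative marker, so boundary error is measured in marker
units: the number of informative markers strictly between the detected
and true boundary. A boundary is recovered "within k marker spacings"
when that count is ≤ k. With the default marker densities the bp gap
between truth and the first informative marker is approximately
exponential with mean ~1 kb — a floor no algorithm can beat — while the
marker-unit error is 0 for any correct caller unless noise removes
boundary markers. The acceptance sweep requires both locus boundaries
within 3 marker spacings in ≥95 of 100 seeded simulations; observed
recovery is 99–100/100, with a median bp error near the ~1 kb marker
spacing floor. Signed bp errors are also reported
(`truth_boundary_error`) for descriptive use.

## Recessive candidate filter

Inside the locus, a candidate must be hom-alt in every prone sequenced
strain and hom-ref in every resistant one. "Absent in the resistant
strain" is read as hom-ref; a missing genotype is never evidence for
either presence or absence and excludes the call. The filter is
idempotent, anti-monotone in panel size, and equal (tested on 100
instances of 10,000 random calls) to a brute-force per-strain
predicate-set intersection. Counts are made on decomposed biallelic
records.

## Structural variants

SVs of identical type cluster when reciprocal overlap —
min(overlap/len_a, overlap/len_b) — is at least 0.8; INS and BND cluster
by breakpoint distance ≤ 50 bp. Linkage is transitive; a sorted sweep
with union-find reproduces the all-pairs transitive closure (tested).
Both thresholds are config-exposed since there is no field-wide standard.
A strain supports a cluster when any member call is het or hom-alt;
prone-specific clusters are those supported in every prone strain and no
resistant one.

## Consequence annotation

A deliberately minimal re-implementation of consequence calling: only
gene/mRNA/CDS features are used, only the first transcript per gene is
annotated, and classes are missense, synonymous, stop_gained, stop_lost,
noncoding, and a `cds_indel` umbrella (no frameshift/in-frame subtyping,
no splice or UTR classes). For an exonic SNV the affected codon is
rebuilt across exon junctions from the phase-adjusted CDS offset,
reverse-complemented for minus-strand genes, and translated with the
standard nuclear code; protein position is offset//3 + 1 and changes are
reported as `XposY` (e.g. H148R). The REF allele is checked against the
supplied sequence to catch genome-build mismatches. The oracle test
splices and translates the entire CDS for both alleles and diffs the
proteins — 1,000 random multi-exon genes on both strands, plus
strand-mirror symmetry, at 100% agreement.

Substitution-tolerance (SIFT-style) scores are consumed from a lookup
table, never computed (score computation needs protein alignments, out of
scope); scores below 0.05 (strict) are labeled deleterious, per the usual
convention, so an exact 0.05 is tolerated.

## Segregation scoring

Across a wider strain panel the expected pattern under the recessive
model is: allele present iff the strain is prone. Presence/absence comes
from a table (standing in for assembly lookups); every candidate must
have a row. Results list per-strain violations and sort fully-concordant
candidates first, then by violation count and position — mirroring the
qualitative argument that isolates a single concordant missense variant,
with no numeric prior weighting.

## Synteny liftover and interval screens

The homology map is an explicit input: a TSV of colinear equal-length
blocks (per-base bijective within a block), because no single homology
resource is canonical. A minus-strand block reflects coordinates within
the block. The lifted result reports the mapped pieces, the bounding hull
on the majority destination chromosome (a single human-style interval),
and the mapped fraction. Per-base bijectivity through inversions is
verified by round-trip on 1,000 random intervals. Peak overlap uses an
any-overlap (≥1 bp) criterion against the hull; the association screen is
a pure interval query returning rows sorted by p-value, with no
statistics recomputed.

## The synthetic cross generator

The generator emulates the breeding design, not its population genetics:
derived genomes are genotype-label mosaics copied from the parents at
placed breakpoints; no recombination process, read-level data, or
realistic recombination map is simulated. Defaults define the study
conditions:

| parameter | default | meaning |
|---|---|---|
| chrom_length | 20 Mb | chromosome-13 analog (desk-scale) |
| introgressed_segment | [10, 12) Mb | true donor fragment |
| donor/recipient_marker_rate | 1/2,000 bp each | strain-specific hom variants |
| shared_variant_rate | 1/5,000 bp | hom-alt in both parents |
| indel_fraction | 0.1 | indels among markers |
| n_extra_mosaic_segments | 3 × 500 kb | extra donor segments in the ASC-like strain |
| genotype_error_rate | 1e-3 | per-call uniform flip to a wrong state |
| missing_rate | 1e-3 | per-call missingness |
| n_genes | 8 (half in-segment) | multi-exon gene models, both strands |
| n_sv_specific / n_sv_background | 3 / 10 | planted prone-specific and background SVs |
| n_peaks_inside / n_dys_inside | 76 / 5 | peak pattern in the lifted locus |

Noise is applied per call after truth recording; an error flips the state
to one of the two wrong concrete states with equal probability. Noise
applies to SNV/indel genotypes only — SV genotypes stay clean so the
planted specificity set is an exact expectation. One RNG stream is seeded
once, and sub-generators draw in a fixed order (chromosome sequences,
gene planting, causal and synonymous CDS variants, marker
positions/alleles per chromosome and class, mosaic extra segments, SVs,
synteny permutation, peaks, association rows, noise), making all outputs
byte-identical per seed.

Random background variants avoid CDS footprints; the CDS-hitting
donor-specific variants are planted explicitly — a configurable number of
synonymous changes at random degenerate codon positions plus exactly one
causal missense (default H at protein position 148 to R, reachable by a
single substitution; the generator searches the codon table and errors
with the admissible substitutions if the requested change needs two).
This makes the downstream consequence expectations exact by construction.
In-locus peaks and association rows are placed with a small interior
margin (≤25 kb) so that truth counts are insensitive to the ~kb
marker-resolution shave of the detected locus; boundary-straddling peaks
are not a useful truth condition.

What passing tests do **not** show about real data: real congenic genomes
have non-uniform marker density, linked genotyping artifacts (the noise
here is independent per call), segmental duplications confusing SV calls,
and transcript-annotation ambiguity (e.g. protein positions that differ
between transcript numberings); the generator models none of these.

## Pipeline

Stages exchange plain files (VCF 4.2, GFF3, FASTA, BED4, TSV, JSON); the
run config is schema-validated (unknown keys rejected) before any stage
executes, and a stage failure halts the run naming the stage. The report
asserts count consistency (candidates ≤ in-locus calls; missense ≤
candidates). Reruns are byte-identical apart from the `timings_s` block —
wall-clock is the one field that cannot be stable, so determinism is
defined over the report with timings excluded.

## Problem sizes

The default 20 Mb / one-chromosome configuration gives ~24,000 variant
calls and ~20,000 informative markers per simulation; the acceptance
sweep uses 100 seeds and the oracle checks use 100 × 10,000-call
instances (recessive filter), 100 × ≤200-marker instances (segment
caller), and 1,000 random cases each for the consequence caller and
liftover round trip.
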