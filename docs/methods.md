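# Methods

This note documents the models and procedures implemented in `irmutscan`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Filter chain

The pipeline assumes per-sample small-variant calls from a treated /
untreated experimental design in which treated cultures derive from the
same cell line as the controls. Under that assumption, any call shared
with the pooled controls is pre-existing rather than induced, and removal
by exact (chrom, pos, ref, alt) identity is appropriate; genotype is
deliberately ignored because the controls act as a variant *pool*, not a
genotyped cohort. The control pool defaults to the global union over all
control samples; interval-matched pools can be passed instead by calling
`run_filter_chain` per interval with the matching pool.

Coverage filtering uses inclusive minima DP ≥ 3 and GQ ≥ 20 ("a value of
3" reads as a minimum). Records lacking DP or GQ are retained and counted
separately: a missing FORMAT field is a caller artifact, and silently
coercing it to 0 would delete the record for the wrong reason.

The binomial filter asks whether the alternate-read support of a call is
explainable by sequencing error alone: with per-base error rate
*e* = 0.001 and X ~ Binomial(DP, *e*), the exact one-sided tail
p = P(X ≥ AD_alt) is computed with `scipy.stats.binom.sf` and the call is
retained iff p < α (default 0.001, configurable). The direction —
retain-iff-significant — follows from the filter's purpose (removing
sequencing artifacts); testing against reference contamination instead
would be the mirrored parameterization and can be obtained by passing the
appropriate error rate. Calls without an AD field skip the test with a
warning rather than being removed on absent evidence. Numerically, the
scipy tail agrees with an exact integer-arithmetic summation to better
than 10⁻¹³ relative wherever the tail exceeds 10⁻²⁵⁰; deeper tails exceed
what double precision represents and are ~250 orders of magnitude below
any usable α, so their exact values are irrelevant to the decision.

The three stage predicates are mutually independent, so the *retained
set* is invariant to stage order and the chain is idempotent; the
per-stage removal tallies are reported for the canonical order
sample → coverage → binomial and do depend on that order (each stage only
sees the survivors of the previous one).

## Accumulation, Ti/Tv, gene density

Band accumulation is length-normalized: V/Mb = 10⁶ · count / (end −
start). Variants use VCF 1-based positions, intervals BED 0-based
half-open coordinates; every containment test converts a variant position
to pos − 1. Transitions are A↔G and C↔T; Ti/Tv is the plain count ratio
and is reported as absent when the transversion count is zero.
Multi-nucleotide substitutions (ref and alt the same length > 1) are
excluded from Ti/Tv and tallied separately, since the ratio is defined
for single-base substitutions. The gene-density association is Pearson's
r (the modeled relationship is linear); Spearman is available via the
`method` flag. Gene density is an input table, not computed from
annotation, because published per-chromosome densities depend on the gene
set chosen.

## TAD binning

Overlapping input TADs are merged (with a warning) before gap
computation, because the inside/outside ratio and partition conservation
require a partition; gaps are the maximal uncovered intervals *including
chromosome ends*. Each domain or gap is split into 10 portions by the
proportional-floor rule bin = ⌊(pos − 1 − start) · 10 / length⌋, so bin
widths differ by at most 1 bp when the length is not divisible by 10.
Bins run in genomic orientation for TADs and gaps alike (gaps are not
mirrored). Intervals shorter than the bin count fall back to a single bin
with a warning. The boundary-enrichment score — mean of the two edge bins
over the mean of the eight interior bins, absent when the interior is
empty — is this package's operationalization of "accumulation at domain
borders"; it is 1 in expectation under uniform placement.

## InDel signatures

InDels are typed by allele-length difference (more reference bases than
alternate = deletion, fewer = insertion), the single left VCF anchor base
is stripped, and the event sequence S is compared against the flanking
reference with precedence **rep > mh > none**:

- *rep*: at least one full additional copy of S adjacent to the event —
  the downstream reference begins with S or the upstream reference ends
  with S. A full copy is stronger evidence of replication slippage than
  partial homology, hence the precedence. The repeat check is
  deliberately symmetric across flanks: for left-aligned VCF records the
  copy always lies downstream and the two rules coincide, but the
  symmetric rule additionally makes classification invariant under
  reverse complementation of the locus for arbitrary (non-normalized)
  input. Variants are classified as given; left-alignment of the input is
  the caller's responsibility.
- *mh*: the largest m with 1 ≤ m < |S| such that the first m bases of S
  equal the first m bases of the downstream flank, or the last m bases of
  S equal the last m bases of the upstream flank; bimh ("biggest InDel
  microhomology") is that maximum over both flanks. Deletions flanked by
  microhomology are the signature of microhomology-mediated end joining.
- *none*: neither.

Insertions use the same logic with S = the inserted sequence. Near
chromosome ends only the available flank is compared; records whose locus
is absent from the reference, or that are not representable as a single
anchored InDel, are tallied as unresolved. Category sub-lengths (event
length for rep/none, bimh for mh) are bucketed 1…4 with a `5+` overflow
bucket — the cap is configurable; no maximum InDel length is imposed.

Fold changes are per-category log₁₀(count_filtered / count_unfiltered)
with a 0.5 pseudocount substituted for zero cells and categories absent
from both spectra omitted. Log base 10 is used so that uniform retention
of a fraction r gives exactly log₁₀(r) in every category (r = 2% →
−1.70), making the per-type averages directly interpretable as retention
magnitudes.

## Translocation post-processing

Two calls are equal when they join the same unordered chromosome pair and
*both* breakends lie within the same 200-nt window (strict <; the
strictness is a convention and configurable). Equality of a two-breakend
object requires both ends — a single-end window would conflate distinct
junctions. Treated calls equal to any control call are removed; survivors
are deduplicated within the sample keeping the higher-confidence (then
higher-support) call, since the same equality notion that justifies
control subtraction implies within-sample duplicates should not be
counted twice (deduplication can be disabled). Thresholds follow their
phrasing exactly: supporting reads ≥ 20 (inclusive), confidence > 80
(exclusive). Caller orientation strings are ignored for equality.

## Functional-impact summary

Annotations are restricted to RefSeq-known transcripts, identified by
accession prefix (NM_/NR_); this keeps the package independent of any
live RefSeq release. Related SO terms are folded into combined terms via
an explicit table (e.g. `splice_acceptor_variant&intron_variant` →
`splice_site`); unmapped terms pass through. Each distinct combined term
counts once per (chrom, pos, ref, alt) location regardless of transcript
multiplicity, and the location's impact class is the most severe among
its retained annotations — the convention matching one-impact-per-variant
reporting. Locations with no retained annotation count as MODIFIER under
an `unannotated` term (configurable).

## Synthetic-data generator

The generator emulates the statistical structure of a radiation
WGS experiment — six treated samples (0.5/2/10 Gy × 16 h/7 d; dose labels
are metadata only, since no dose–response is modeled) sharing 98% of
their variants with an untreated control pool; Ti/Tv 2.1 for shared vs
1.45 for treatment-specific variants; SNV:InDel 5.2 vs 2.1; per-chromosome
loading spanning a 10× range for induced variants (control loading is
flattened as weights^0.3, giving the ~2× spread expected before
filtering); geometric InDel lengths (p = 0.5, mono/dinucleotide
dominance); a configurable rep/mh/none deletion-context mix realized by
*placement* against the generated reference and validated with the same
classifier the analysis uses; and translocation tables in which a
configured fraction of treated events are < 200-nt-jittered control
copies and read/confidence values straddle the 20/80 thresholds. Small
extra contingents of sequencing-error artifacts (alternate support drawn
from Binomial(DP, 0.001)) and low-DP/GQ calls exercise the second and
third filter stages; they are added beyond the nominal sample size so the
retained fraction stays at (1 − shared fraction)/(1 + extras) ≈ 2%.

Reference sequence is i.i.d. uniform A/C/G/T with implanted
mononucleotide runs (8–12 bp every ~1.5 kb) and dinucleotide tracts
(10–16 bp every ~3 kb) so repeat contexts occur at useful rates. Bands
partition each chromosome into equal parts; TADs cover ~55–80% of each
chromosome with gaps between and around them. DP is Poisson (mean 60,
floor 4) and GQ near-saturated — the experiment these defaults emulate
reports no distributional forms for either, so they are arbitrary and
configurable. The `triplet_none_boost` knob multiplies the 3-nt mass of
the featureless-deletion length distribution *before* normalization,
which makes the boost exactly the odds ratio of 3-nt deletions among
featureless deletions — the closed form the recovery tests use. Optional
`tad_density_boost` and `boundary_bin_boost` weight variant placement
inside TADs and in edge bins. Everything is a deterministic function of
the seed (byte-identical files on re-run).

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: realistic human sequence
composition (GC structure, repeat families, segmental duplications),
read-level errors and mapping artifacts, mutational clustering beyond the
configured weights, dose–response structure, intra-chromosomal SVs, and
caller-specific quirks in VCF representation (e.g. non-left-aligned
InDels). Placement by rejection sampling conditions context classes on
the generated reference; repeat-context deletions of length ≥ 7 are
occasionally unplaceable and resample their class with a warning, biasing
the realized mix by well under 1%.

## Problem sizes and tolerances

Statistical recovery tests run at n = 10,000–20,000 variants per sample
with fixed seeds and assert agreement within 3 standard errors of the
configured value (binomial/multinomial SEs, delta-method SEs for ratios,
log-odds SEs for the boost). The oracle equivalences are exhaustive:
all dp ≤ 200 × all alternate counts for the binomial tail (exact integer
arithmetic), and all 4⁸ reference octamers × all deletions of length ≤ 3
at every anchored position for the context classifier. Uniform-placement
flatness is asserted as a chi-square goodness-of-fit p-value above 0.001.
Translocation recovery is exact because the generator separates novel
events from every other event by ≥ 400 nt on at least one breakend,
making windowed subtraction and deduplication unambiguous.

## Known limitations

- The binomial filter models a single global error rate; no per-base
  quality or strand-bias information is used.
- Signature classification does not left-align or normalize input
  InDels; mis-normalized input shifts contexts (a normalization pass can
  be added upstream with standard tools).
- The boundary-enrichment score is sensitive to domains shorter than a
  few kilobases, where 10 bins approach single-base widths.
- Pearson correlation against gene density on few chromosomes has wide
  sampling variance; with the synthetic 8-chromosome genome the reported
  r fluctuates noticeably across seeds.
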