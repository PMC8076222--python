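# Methods

This note documents the models, rules and numerical choices behind
`tssoverlap`, what the synthetic cohort does and does not emulate, and
the limitations a user should keep in mind.

## Coordinates and data model

All internal coordinates are 0-based half-open; BED input passes
through unchanged and GFF3 (1-based inclusive) is shifted at the I/O
boundary only. A gene's per-library "position" is defined by its
admitted TSS records — only the 3' boundary ever comes from the
annotation, because TSS data move 5' ends but say nothing about 3'
ends.

## TSS admission

A TSS record is admitted when it (i) carries the producer's confidence
flag (the flag's semantics are delegated to the data producer and the
rule can be disabled), (ii) has expression ≥ `min_ppm` (default 5 ppm
— "lower than 5 ppm" is rejected, so exactly 5.0 is admitted), and
(iii) lies within `max_distance_bp` (default 5000) of the annotated 5'
end. The distance is absolute, symmetric in direction: the source
protocol does not state a direction, and the symmetric reading is the
least-assuming one; it is recorded in the rejection report's metadata.
The ppm rule is applied per TSS record; identical positions reported in
several rows for one (gene, library) merge by summing counts before
filtering, making the filter idempotent. Rejections are counted per
rule, first failing rule wins.

## Overlap calling

Within one library, let `a` be the plus gene's effective 5' end (its
minimum admitted TSS position) and `b` the minus gene's (maximum).
Per-library extents are the inclusive base sets `{a .. plus 3'}` and
`{minus 3' .. b}`. The pair overlaps when both genes are expressed,
`b >= a`, and each effective 5' end lies inside the partner's extent;
the shared span is then `[a, b]`, length `b - a + 1 >= 1`. Only the
≥ 1 bp predicate is load-bearing downstream; the length is reported for
inspection. The "each 5' end inside the partner's extent" condition
excludes nested/tandem geometries from being called head-to-head 5'
overlaps; it is configurable (`require_head_to_head=False` gives the
bare shared-base predicate, which is also the variant that is monotone
under upstream 5'-end moves). Candidate pairs are enumerated by
intersecting 5'-extended possible extents (span extended upstream by
`max_gap_bp`, default 10 kb = twice the TSS search radius), which is
provably a superset of every configuration the per-library caller can
ever mark overlapping.

Each expressed gene-library observation is also placed in one of six
categories: {overlap, no_overlap, single_expressed} x {single TSS,
multiple TSSs}, the grid used for the category-stratified expression
comparison.

## Overlap matrix and clustering

Cells are 1 (pair used overlapping TSSs), 0.5 (expression without
overlap — including the case where only one gene is expressed, a
deliberate reading that keeps the alphabet ternary; configurable), and
0 (no expression). Pairs that never overlap are dropped from the
matrix. Both axes are clustered with Ward linkage on Euclidean
distances (Ward presumes Euclidean geometry; the distance is therefore
not configurable). The flat-cut cluster count is a free parameter with
no fidelity claim; the recovery analyses cut at k = 3 because the
synthetic cohort plants three library groups.

## Enrichment

Gene-set enrichment is a one-sided hypergeometric test per reference
set with Benjamini–Hochberg correction across the reported sets. Sets
sharing fewer than 4 genes with the query are dropped before testing,
and rows carry −log10(p) and −log10(FDR), sorted by their sum. This is
a local, fully reproducible replacement for web-service screens; it
deliberately omits any rank-based correction such services layer on
top of Fisher/hypergeometric tests.

## Expression statistics

Contrast pairs are those overlapping in ≥ 10 libraries and
non-overlapping in ≥ 10 others (both genes expressed in every counted
library). Expression is transformed log2(x + 1) before the Pearson
correlations and the paired t-test: expression is heavy-tailed, and
both statistics assume an additive scale. A raw-scale mode exists
(`log_transform=False`). The paired test's unit of pairing is the
gene — each gene's mean over its pair's overlap libraries against its
mean over the non-overlap libraries — matching a gene-level reading of
stratified expression; a per-pair-summed alternative would halve the
units and is not implemented. Correlation verdicts use alpha = 0.05
two-sided with no multiplicity correction, mirroring
count-of-significant-pairs reporting; treat the counts descriptively,
not inferentially. Zero-variance strata yield an undefined r reported
as "ns". The degenerate paired test with identical differences returns
t = 0, p = 1 (all-zero) or ±inf, p = 0 (constant shift) rather than
NaN.

## Allele-specific expression

The three classes partition minor-allele-fraction space: f < 0.02
monoallelic, 0.02 ≤ f < 0.20 skewed, f ≥ 0.20 biallelic. The
minor-fraction formulation is an interpretation: the verbal
rules ("at least 98% to one allele / less than 2% to the second", "less
than 20% ... and at least 2% ...") are mutually consistent only when
read on the minor allele, and the boundary assignments follow the "at
least" wording (f = 0.02 → skewed, f = 0.20 → biallelic). SNPs need
depth ≥ 10 (boundary retained) and must lie outside the pair's overlap
region, taken as the union over libraries of called overlap spans —
the conservative choice, since reads from a shared span cannot be
attributed to one gene and mimic biallelic signal even under strict
allele-specific expression of both genes. Within a (gene, library),
unanimous SNP classes give the class and any disagreement gives
"noninformative"; across libraries, uniform informative classes give
the overall call and discordant ones give "mixed". Genes are excluded
up front when they never reach 5 FPKM (exactly 5 counts as expressed)
or when their span touches a nondiploid region. Heterozygosity
detection, alignment and per-allele counting are upstream of this
package by design; allele counts arrive as a table.

## Promoter switches and TF association

A pair switches when it is non-overlapping in *every* control library
and overlapping in *every* treated library (universal quantifiers; a
3-of-4 treated pattern is not an event). Switching genes are those
whose effective 5' end differs between conditions, with the
condition-level 5' end taken as the most upstream admitted TSS across
the condition's libraries; shifts are strand-aware (positive =
upstream) and `new_tss_is_additional` records whether the control TSS
is still admitted after treatment. DE results are consumed, not
fitted: up means log2FC > 1.5 and FDR < 0.05, both strict, matching
"higher than 1.5" / "smaller than 0.05". A TF associates with a TSS
when a motif hit's midpoint lies within 500 bp (inclusive, symmetric —
the window is described as upstream and downstream); midpoint anchoring
is a choice the hit-edge alternative can replace via the motif-length
table. TSS-specific means associated with exactly one of the gene's
TSSs.

## Motif scanning

A PFM becomes a log-odds PWM via a total pseudocount split by the
background: `log2(((count + pc*bg_b) / (colsum + pc)) / bg_b)` with
uniform background and pc = 0.8 — conventional defaults, both
configurable and recorded in output metadata. Scores are min-max
normalised over all possible words; a hit needs relative score ≥ 0.95,
the standard meaning of a "95% significance score" in PWM scanning
tools. Both strands are scanned; reverse-strand scoring uses the
reverse-complemented matrix so hits land on forward coordinates.
Windows containing N are skipped. No p-value calibration is attempted.

## Synthetic cohort

The generator is the package's study-conditions definition, not a
tuning knob. Defaults: 200 pairs in three groups, plus 5 constitutive
and 5 switch pairs; three library groups of 10 with within-group
overlap propensity 0.9 against 0.4 across; per-gene expression
probability 0.95; TSS expression ≥ 5 ppm (all planted real TSSs are
admissible) plus 9 planted reject-able records per library (low ppm,
non-confident, too distant); expression log-normal with baseline
N(4, 1.5²) on the log2 scale, σ = 1 library noise, a 0.5 log2-unit
uplift when the pair overlaps, and pairwise correlation ρ = 0.5
induced by a shared latent factor — the simplest mechanism giving a
controllable Pearson ρ; binomial allele counts at minor fractions
0.005/0.10/0.45 (straddling the 2% and 20% thresholds with margin)
with depth 30 + Poisson, 2–4 SNPs per gene, planted overlap-region and
low-depth SNPs that the filters must remove, and a 20% share of
"mixed" genes with discordant per-library classes; a 2-control /
4-treated switch scenario whose movers shift 1225 bp upstream (the
non-overlapping TSS sits 1200 bp from the overlap midpoint so that a
±500 bp motif window can never reach both TSSs); and strong consensus
PFMs for a planted up-regulated activator (motif near the new TSS
only) and a down-regulated repressor (near the old TSS only).
Accidental exact-consensus matches in the random promoter background
are mutated away so the planted instances are the only ones — the
association recall is then a property of the pipeline, not of
background collision luck. Pair geometry puts the two overlapping
TSSs 50 bp apart (overlap length 51 bp) with 8 kb genes spaced 50 kb
apart, so candidate search never crosses loci.

In the six condition libraries, non-switch pairs draw one state and
keep it across all six — replicate cell-line conditions reuse a
consistent TSS choice — which also makes the planted switch pairs the
only condition-consistent switches, so switch precision is a sharp
metric rather than a background-rate gamble.

What the cohort does **not** emulate: real promoter sequence
composition (random ACGT background), read-level noise, mapping
artefacts, overdispersed allele counts (pure binomial), correlated
TSS usage between neighbouring pairs, CNV-driven allelic imbalance and
imprinting structure, or the long-tailed library-size variation of
real TSS-seq data. Passing recovery tests therefore demonstrates the
pipeline's correctness under its stated assumptions, not robustness to
those real-data complications.

## Problem sizes

The test suite and the acceptance script run the standard cohort (200
pairs x 36 libraries, ≈ 20,000 TSS records, ≈ 5,500 SNPs), 1,000
randomized overlap configurations against the base-set oracle,
exhaustive SNP classification to depth 200, 20 seeds of the clustering
scenario, and 200 replicates of the paired-test power simulation —
sizes chosen so the full suite completes in about half a minute while
keeping every law-of-large-numbers check comfortably powered.

## Known limitations

* The overlap caller is genomic-span based; it does not ask whether
  the shared span is exonic in both transcripts.
* Tail-to-tail and fully nested overlap classes are out of scope.
* The ASE module performs no phasing and cannot separate random
  monoallelic expression from imprinting; a bulk biallelic signal may
  hide cell-level monoallelic expression.
* The enrichment test conditions only on set membership; it ignores
  gene length, expression level and other covariates real screens
  confound on.
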