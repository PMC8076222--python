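# tssoverlap

Library-resolved analysis of protein-coding gene pairs that overlap at
their 5' ends.

## The problem

Many human genes sit head-to-head on opposite strands, and whether two
such genes actually share sequence at their 5' ends is not a fixed
property of the genome: it depends on which alternative transcription
start site (TSS) each gene uses in each tissue, cell line or condition.
A promoter switch can toggle a pair between overlapping (a candidate
for transcriptional interference or sense–antisense regulation) and
non-overlapping arrangements. `tssoverlap` takes per-library TSS
tables, gene models, expression tables, allele read counts,
differential-expression results and promoter sequences, and answers,
per library:

* which TSSs are credible (confidence flag, expression ≥ 5 ppm, within
  5 kb of the annotated 5' end);
* which head-to-head pairs share at least 1 bp at their 5' ends, taking
  each gene's **most upstream** admitted TSS as its effective 5' end;
* how the pair-by-library overlap pattern clusters (Ward linkage on the
  ternary matrix with cells 1 = overlap, 0.5 = expression without
  overlap, 0 = no expression);
* whether genes are expressed differently when their pair overlaps
  (per-pair Pearson correlations within overlap / non-overlap library
  strata; a paired *t*-test of per-gene mean log2 expression between
  strata; Mann–Whitney *U* comparisons across TSS-count groups and the
  six organization x TSS-count categories);
* which genes show monoallelic, skewed or biallelic allele usage
  (minor-allele read fraction *f* = min(ref, alt)/depth with classes
  *f* < 0.02, 0.02 ≤ *f* < 0.20, *f* ≥ 0.20; SNPs need depth ≥ 10 and
  must lie outside the pair's overlap region; genes need ≥ 5 FPKM
  somewhere and a diploid locus);
* which pairs switch from non-overlapping in every control library to
  overlapping in every treated library, which gene moved its 5' end
  upstream, and which differentially expressed transcription factors
  (|log2FC| > 1.5, FDR < 0.05) have binding-site motifs (PWM relative
  score ≥ 0.95) within 500 bp of exactly one of the gene's TSSs.

Real cohorts of this shape come from TSS-seq/CAGE databases and paired
WGS/RNA-seq studies; the package ships a synthetic-data generator that
emulates their statistical structure with planted ground truth, so the
entire pipeline is testable end to end without downloads.

## Worked example

```python
from tssoverlap import FilterConfig, filter_tss, candidate_pairs, call_all, pair_library_summary
from tssoverlap.matrix import build_overlap_matrix, cluster_bidirectional
from tssoverlap.simulate import SimConfig, generate

bundle = generate(SimConfig(seed=1))
admitted, report = filter_tss(bundle.tss_records, bundle.genes, FilterConfig())
print(f"admitted {report.n_admitted}/{report.n_input} TSS records; rejections: {report.by_rule}")

pairs = candidate_pairs(bundle.genes)
statuses = call_all(pairs, bundle.genes, admitted, bundle.all_library_ids)
summary = pair_library_summary(statuses)
print(f"{len(pairs)} candidate pairs; "
      f"{int((summary.per_pair['n_libraries_overlap'] > 0).sum())} overlap somewhere; "
      f"{len(summary.always_overlap)} overlap in every co-expressed library")

matrix = build_overlap_matrix(statuses)
clust = cluster_bidirectional(matrix[bundle.config.library_ids()], 3, 3)
print(f"matrix {matrix.shape[0]} pairs x {matrix.shape[1]} libraries; "
      f"grouped-library cluster sizes {clust.col_labels.value_counts().sort_index().tolist()}")
```

prints

```
admitted 19953/20222 TSS records; rejections: {'low_ppm': 89, 'not_confident': 90, 'too_distant': 90}
210 candidate pairs; 210 overlap somewhere; 5 overlap in every co-expressed library
matrix 210 pairs x 36 libraries; grouped-library cluster sizes [10, 10, 10]
```

The 269 rejected records are exactly the planted sub-threshold,
non-confident and too-distant TSSs (plus sub-threshold merges); the 5
always-overlapping pairs are the 5 planted constitutive pairs; and
cutting the Ward dendrogram of the 30 grouped libraries at k = 3
recovers the three planted library groups exactly (adjusted Rand index
1.0).

The same analysis runs from the shell:

```bash
tssoverlap simulate --seed 1 --out run/
tssoverlap run-all run/          # writes statuses.tsv, overlap_matrix.tsv,
                                 # ase_calls.tsv, switch_events.tsv, ...,
                                 # manifest.json and recovery.json
```

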