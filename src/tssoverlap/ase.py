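"""Allele-specific expression classification.

A heterozygous SNP's class is decided by its minor-allele read
fraction ``f = min(ref, alt) / (ref + alt)``:

* ``f < 0.02``  -> monoallelic (>= 98% of reads on one allele),
* ``0.02 <= f < 0.20`` -> skewed,
* ``f >= 0.20`` -> biallelic.

The three intervals partition [0, 0.5], so every count pair gets
exactly one class.  SNPs below ``min_depth`` reads (default 10) or
inside a pair's 5'-overlap region are discarded first — reads from the
shared span cannot be attributed to one gene and would mimic biallelic
signal even under strict allele-specific expression of both genes.

Per gene and library, unanimous SNP classes give the gene that class;
any disagreement is noninformative.  Across libraries, uniform
informative classes give the overall call, discordant ones give
"mixed".  Genes never reaching ``min_fpkm`` in any library, or lying
in nondiploid genome regions, are excluded up front.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import fisher_exact

from .models import AlleleCount, AseCall, GeneModel, RegionMask

DEFAULT_MIN_DEPTH = 10
DEFAULT_MIN_FPKM = 5.0
MONO_MAX_FRACTION = 0.02
BIALLELIC_MIN_FRACTION = 0.20

SNP_CLASSES = ("monoallelic", "skewed", "biallelic")


def classify_snp(ref_count: int, alt_count: int) -> str:
    """Class of one SNP from its minor-allele read fraction."""
    depth = ref_count + alt_count
    if depth < 1:
        raise ValueError("cannot classify a SNP with zero depth")
    f = min(ref_count, alt_count) / depth
    if f < MONO_MAX_FRACTION:
        return "monoallelic"
    if f < BIALLELIC_MIN_FRACTION:
        return "skewed"
    return "biallelic"


def usable_snps(
    counts: Sequence[AlleleCount],
    overlap_mask: RegionMask | None = None,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> list[AlleleCount]:
    """SNPs deep enough and outside any called overlap region.

    ``overlap_mask`` is the union over libraries of called overlap
    spans (see :func:`overlap_regions_mask`); the union is the
    conservative choice when spans differ between libraries.
    """
    out = []
    for c in counts:
        if c.depth < min_depth:
            continue
        if overlap_mask is not None and overlap_mask.contains(c.chrom, c.pos):
            continue
        out.append(c)
    return out


def overlap_regions_mask(statuses: Iterable, genes: Mapping[str, GeneModel]) -> RegionMask:
    """Union of every pair's called overlap spans across libraries.

    Overlap spans are inclusive ``[a, b]``; stored half-open.
    """
    mask = RegionMask(label="overlap")
    seen = set()
    for s in statuses:
        if s.state != "overlap" or s.five_prime_plus is None or s.five_prime_minus is None:
            continue
        gene_plus = s.pair_id.split("|")[0]
        chrom = genes[gene_plus].chrom
        key = (chrom, s.five_prime_plus, s.five_prime_minus + 1)
        if key not in seen:
            seen.add(key)
            mask.add(*key)
    return mask


def classify_gene_library(snp_classes: Sequence[str]) -> str:
    """Unanimous SNP classes give the class; any conflict is noninformative."""
    if not snp_classes:
        raise ValueError("need at least one usable SNP")
    unique = set(snp_classes)
    if len(unique) == 1:
        return next(iter(unique))
    return "noninformative"


def aggregate_gene(per_library: Mapping[str, str]) -> str:
    """Overall class across libraries.

    Uniform informative classes give that class; discordant informative
    classes give "mixed"; all-noninformative stays noninformative.
    """
    informative = {c for c in per_library.values() if c != "noninformative"}
    if not informative:
        return "noninformative"
    if len(informative) == 1:
        return next(iter(informative))
    return "mixed"


@dataclass
class ExclusionReport:
    analyzable: list[str]
    excluded: dict[str, str]  # gene_id -> reason

    def partition_ok(self, genes: Iterable[str]) -> bool:
        return set(self.analyzable) | set(self.excluded) == set(genes) and not (
            set(self.analyzable) & set(self.excluded)
        )


def exclude_genes(
    genes: Sequence[GeneModel],
    nondiploid_mask: RegionMask | None,
    expression: pd.DataFrame,
    min_fpkm: float = DEFAULT_MIN_FPKM,
) -> ExclusionReport:
    """Keep genes expressed at >= min_fpkm somewhere and fully diploid.

    Exclusion reasons: ``low_expression`` (never reaching min_fpkm in
    any library) and ``nondiploid`` (span intersects the mask).
    Nondiploidy is checked first.
    """
    analyzable, excluded = [], {}
    for g in genes:
        if nondiploid_mask is not None and nondiploid_mask.overlaps_span(
            g.chrom, g.span_start, g.span_end
        ):
            excluded[g.gene_id] = "nondiploid"
            continue
        expr = (
            expression.loc[g.gene_id]
            if g.gene_id in expression.index
            else pd.Series(dtype=float)
        )
        if expr.empty or float(expr.max()) < min_fpkm:
            excluded[g.gene_id] = "low_expression"
            continue
        analyzable.append(g.gene_id)
    return ExclusionReport(analyzable=analyzable, excluded=excluded)


def classify_genes(
    counts: Sequence[AlleleCount],
    analyzable_genes: Iterable[str],
    overlap_mask: RegionMask | None = None,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> list[AseCall]:
    """Full per-gene classification from raw allele counts.

    Genes without any usable SNP get ``excluded_reason="no_snps"``.
    """
    analyzable = sorted(set(analyzable_genes))
    usable = usable_snps(counts, overlap_mask, min_depth)
    by_gene: dict[str, dict[str, list[str]]] = {}
    n_snps: dict[str, int] = {}
    for c in usable:
        if c.gene_id not in set(analyzable):
            continue
        by_gene.setdefault(c.gene_id, {}).setdefault(c.library_id, []).append(
            classify_snp(c.ref_count, c.alt_count)
        )
        n_snps[c.gene_id] = n_snps.get(c.gene_id, 0) + 1

    calls = []
    for gene in analyzable:
        if gene not in by_gene:
            calls.append(AseCall(gene_id=gene, excluded_reason="no_snps"))
            continue
        per_lib = {
            lib: classify_gene_library(classes) for lib, classes in by_gene[gene].items()
        }
        calls.append(
            AseCall(
                gene_id=gene,
                per_library=per_lib,
                overall=aggregate_gene(per_lib),
                n_snps_used=n_snps[gene],
            )
        )
    return calls


@dataclass
class MaeSummary:
    counts: dict[str, dict[str, int]]  # set name -> class -> count
    ratios: dict[str, float | None]  # mono/biallelic ratio per set (None if undefined)
    fisher_odds: float
    fisher_p: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for set_name, cc in self.counts.items():
            row = {"set": set_name, **cc, "mono_biallelic_ratio": self.ratios[set_name]}
            rows.append(row)
        return pd.DataFrame(rows)


def mae_summary(
    overlap_calls: Sequence[AseCall], control_calls: Sequence[AseCall]
) -> MaeSummary:
    """Class composition of overlap vs control sets, the mono:biallelic
    ratio in each, and a Fisher exact comparison of that composition."""
    classes = ("monoallelic", "skewed", "biallelic", "mixed", "noninformative")

    def tally(calls: Sequence[AseCall]) -> dict[str, int]:
        cc = {k: 0 for k in classes}
        for c in calls:
            if c.excluded_reason is None:
                cc[c.overall] += 1
        return cc

    counts = {"overlap": tally(overlap_calls), "control": tally(control_calls)}
    ratios = {
        name: (cc["monoallelic"] / cc["biallelic"] if cc["biallelic"] > 0 else None)
        for name, cc in counts.items()
    }
    table = [
        [counts["overlap"]["monoallelic"], counts["overlap"]["biallelic"]],
        [counts["control"]["monoallelic"], counts["control"]["biallelic"]],
    ]
    odds, p = fisher_exact(table)
    return MaeSummary(counts=counts, ratios=ratios, fisher_odds=float(odds), fisher_p=float(p))


def calls_to_frame(calls: Sequence[AseCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "gene_id": c.gene_id,
                "overall": c.overall if c.excluded_reason is None else "",
                "n_snps_used": c.n_snps_used,
                "excluded_reason": c.excluded_reason or "",
                "per_library": ";".join(f"{k}={v}" for k, v in sorted(c.per_library.items())),
            }
        )
    return pd.DataFrame(rows)
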