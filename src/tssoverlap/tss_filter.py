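"""TSS admission rules and per-library usage statistics.

Three rules decide whether an observed TSS is used downstream:

1. confidence — only records flagged confident by the data producer;
2. expression — records below ``min_ppm`` (default 5 ppm) are rejected
   (strictly below: exactly 5 ppm is admitted);
3. distance — the TSS must lie within ``max_distance_bp`` (default
   5 kb) of the gene's annotated 5' end, measured as absolute genomic
   distance in either direction (exactly 5000 bp is admitted).

Identical positions reported in several rows for the same
(gene, library) merge before filtering: raw counts sum, ppm sums, and
the merged record is confident only if every contributing row was.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .models import GeneModel, TssRecord

DEFAULT_MIN_PPM = 5.0
DEFAULT_MAX_DISTANCE_BP = 5000


@dataclass(frozen=True)
class FilterConfig:
    min_ppm: float = DEFAULT_MIN_PPM
    max_distance_bp: int = DEFAULT_MAX_DISTANCE_BP
    require_confident: bool = True

    def __post_init__(self) -> None:
        if self.min_ppm < 0 or self.max_distance_bp < 0:
            raise ValueError("filter thresholds must be nonnegative")


@dataclass
class RejectionReport:
    """Counts of rejections per rule (a record counts once, first rule wins)."""

    n_input: int = 0
    n_admitted: int = 0
    by_rule: dict[str, int] = field(default_factory=dict)

    def reject(self, rule: str) -> None:
        self.by_rule[rule] = self.by_rule.get(rule, 0) + 1

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": k, "n_rejected": v} for k, v in sorted(self.by_rule.items())]
        rows.append({"rule": "admitted", "n_rejected": self.n_admitted})
        return pd.DataFrame(rows)


def compute_ppm(raw_count: int, library_total: int) -> float:
    """Tags per million: ``raw_count / library_total * 1e6``."""
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    if raw_count < 0:
        raise ValueError("raw_count must be nonnegative")
    return raw_count / library_total * 1e6


def merge_duplicate_tss(records: Iterable[TssRecord]) -> list[TssRecord]:
    """Merge rows sharing (gene, library, strand, position).

    ppm and raw counts sum across duplicates; the merged record is
    confident only when all merged rows are.
    """
    merged: dict[tuple, TssRecord] = {}
    for r in records:
        key = (r.gene_id, r.library_id, r.strand, r.position)
        prev = merged.get(key)
        if prev is None:
            merged[key] = r
        else:
            raw = None
            if prev.raw_count is not None and r.raw_count is not None:
                raw = prev.raw_count + r.raw_count
            merged[key] = TssRecord(
                gene_id=r.gene_id,
                library_id=r.library_id,
                chrom=r.chrom,
                strand=r.strand,
                position=r.position,
                expression_ppm=prev.expression_ppm + r.expression_ppm,
                raw_count=raw,
                confident=prev.confident and r.confident,
            )
    return list(merged.values())


def filter_tss(
    records: Sequence[TssRecord],
    genes: Iterable[GeneModel],
    config: FilterConfig = FilterConfig(),
) -> tuple[list[TssRecord], RejectionReport]:
    """Apply the three admission rules; returns admitted records + report.

    Every record's gene must exist in ``genes``.  Duplicate rows merge
    first (see :func:`merge_duplicate_tss`), so the operation is
    idempotent on its own output.
    """
    gene_index = {g.gene_id: g for g in genes}
    unknown = {r.gene_id for r in records} - set(gene_index)
    if unknown:
        raise KeyError(f"TSS records reference unknown genes: {sorted(unknown)[:5]}")

    merged = merge_duplicate_tss(records)
    report = RejectionReport(n_input=len(merged))
    admitted: list[TssRecord] = []
    for r in merged:
        gene = gene_index[r.gene_id]
        if config.require_confident and not r.confident:
            report.reject("not_confident")
        elif r.expression_ppm < config.min_ppm:
            report.reject("low_ppm")
        elif abs(r.position - gene.annotated_five_prime) > config.max_distance_bp:
            report.reject("too_distant")
        else:
            admitted.append(r)
    report.n_admitted = len(admitted)
    return admitted, report


def tss_usage_stats(records: Sequence[TssRecord]) -> pd.DataFrame:
    """Per-library TSS usage summary from already-admitted records.

    Returns a frame indexed by library with ``n_genes``, ``n_tss``
    (distinct positions summed over genes) and ``mean_tss_per_gene``
    (NaN for an empty library).
    """
    if not records:
        return pd.DataFrame(columns=["n_genes", "n_tss", "mean_tss_per_gene"])
    df = pd.DataFrame(
        {
            "library_id": [r.library_id for r in records],
            "gene_id": [r.gene_id for r in records],
            "position": [r.position for r in records],
        }
    )
    per_gene = (
        df.drop_duplicates(["library_id", "gene_id", "position"])
        .groupby(["library_id", "gene_id"])
        .size()
        .rename("n_tss")
    )
    stats = per_gene.groupby("library_id").agg(n_genes="size", n_tss="sum")
    stats["mean_tss_per_gene"] = stats["n_tss"] / stats["n_genes"]
    return stats


def tss_count_per_gene_library(records: Sequence[TssRecord]) -> pd.Series:
    """Distinct admitted TSS count per (gene, library)."""
    if not records:
        return pd.Series(dtype=int)
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "library_id": [r.library_id for r in records],
            "position": [r.position for r in records],
        }
    )
    return (
        df.drop_duplicates()
        .groupby(["gene_id", "library_id"])
        .size()
        .rename("n_tss")
    )
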