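"""Readers and writers for every external format the pipeline touches.

This is the only module allowed to shift coordinates: BED input is
0-based half-open and passes through unchanged; GFF3 (1-based inclusive)
is converted on read and re-converted on write.  Everything downstream
sees a single convention.

All text readers are gzip-transparent (a ``.gz`` suffix is handled
automatically).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs

from .models import AlleleCount, GeneModel, Pfm, RegionMask, TssRecord

logger = logging.getLogger(__name__)

TSS_COLUMNS = ["library_id", "gene_id", "chrom", "strand", "position"]
ALLELE_COLUMNS = ["chrom", "pos", "gene_id", "library_id", "ref_count", "alt_count"]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def _open(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass
class LoadReport:
    """Per-file accounting of rows read, kept and skipped."""

    n_rows: int = 0
    n_kept: int = 0
    skipped: dict[str, int] = field(default_factory=dict)

    def skip(self, reason: str) -> None:
        self.skipped[reason] = self.skipped.get(reason, 0) + 1


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path, format: str = "BED12") -> list[GeneModel]:
    """Read gene models from BED (6 or 12 column) or GFF3.

    GFF3 coordinates (1-based inclusive) are shifted to 0-based
    half-open.  Only rows of type ``gene`` are read from GFF3; the
    ``ID`` or ``gene_id`` attribute names the gene.
    """
    fmt = format.upper()
    if fmt in ("BED6", "BED12", "BED"):
        return _read_bed_genes(path)
    if fmt == "GFF3":
        return _read_gff3_genes(path)
    raise ValueError(f"unknown gene-model format {format!r}")


def _read_bed_genes(path: str | Path) -> list[GeneModel]:
    out = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}: line {lineno}: expected >= 6 BED columns")
            chrom, start, end, name, _score, strand = parts[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if strand not in ("+", "-"):
                raise ParseError(f"{path}: line {lineno}: unknown strand {strand!r}")
            out.append(GeneModel(name, chrom, strand, start_i, end_i))
    return out


def _read_gff3_genes(path: str | Path) -> list[GeneModel]:
    out = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            if strand not in ("+", "-"):
                raise ParseError(f"{path}: line {lineno}: unknown strand {strand!r}")
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if kv and "=" in kv
            )
            gene_id = attr.get("gene_id") or attr.get("ID")
            if gene_id is None:
                raise ParseError(f"{path}: line {lineno}: no ID/gene_id attribute")
            try:
                # GFF3 is 1-based inclusive; internal is 0-based half-open.
                out.append(GeneModel(gene_id, chrom, strand, int(start) - 1, int(end)))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_gene_models(genes: Iterable[GeneModel], path: str | Path, format: str = "BED6") -> None:
    fmt = format.upper()
    with _open(path, "wt") as fh:
        for g in genes:
            if fmt in ("BED6", "BED"):
                fh.write(f"{g.chrom}\t{g.span_start}\t{g.span_end}\t{g.gene_id}\t0\t{g.strand}\n")
            elif fmt == "GFF3":
                fh.write(
                    f"{g.chrom}\t.\tgene\t{g.span_start + 1}\t{g.span_end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id};gene_id={g.gene_id};biotype={g.biotype}\n"
                )
            else:
                raise ValueError(f"unknown gene-model format {format!r}")


# ---------------------------------------------------------------------------
# TSS tables
# ---------------------------------------------------------------------------

def read_tss_table(
    path: str | Path,
    genes: Iterable[GeneModel] | None = None,
    library_totals: dict[str, int] | None = None,
) -> tuple[list[TssRecord], LoadReport]:
    """Read a per-library TSS table.

    The table is tab-separated with a header naming at least
    ``library_id, gene_id, chrom, strand, position`` plus either
    ``expression_ppm`` or ``raw_count`` (ppm is then computed from the
    per-library total, taken from ``library_totals`` or, failing that,
    from the sum of raw counts per library in the file).  Rows
    referencing a gene absent from ``genes`` are skipped with a warning
    and counted in the report.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in TSS_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing TSS columns {missing}")
    has_ppm = "expression_ppm" in df.columns
    has_raw = "raw_count" in df.columns
    if not has_ppm and not has_raw:
        raise ParseError(f"{path}: need expression_ppm or raw_count column")

    if not has_ppm:
        from .tss_filter import compute_ppm

        totals = library_totals or df.groupby("library_id")["raw_count"].sum().to_dict()
        df = df.assign(
            expression_ppm=[
                compute_ppm(int(c), int(totals[lib]))
                for c, lib in zip(df["raw_count"], df["library_id"])
            ]
        )

    known = {g.gene_id for g in genes} if genes is not None else None
    report = LoadReport(n_rows=len(df))
    records: list[TssRecord] = []
    for row in df.itertuples(index=False):
        if known is not None and row.gene_id not in known:
            report.skip("unknown_gene")
            continue
        confident = bool(getattr(row, "confident", True))
        raw = getattr(row, "raw_count", None)
        records.append(
            TssRecord(
                gene_id=row.gene_id,
                library_id=row.library_id,
                chrom=row.chrom,
                strand=row.strand,
                position=int(row.position),
                expression_ppm=float(row.expression_ppm),
                raw_count=None if raw is None or pd.isna(raw) else int(raw),
                confident=confident,
            )
        )
    report.n_kept = len(records)
    if report.skipped:
        logger.warning("%s: skipped rows: %s", path, report.skipped)
    return records, report


def write_tss_table(records: Iterable[TssRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "library_id": r.library_id,
                "gene_id": r.gene_id,
                "chrom": r.chrom,
                "strand": r.strand,
                "position": r.position,
                "expression_ppm": r.expression_ppm,
                "raw_count": "" if r.raw_count is None else r.raw_count,
                "confident": r.confident,
            }
            for r in records
        ],
        columns=TSS_COLUMNS + ["expression_ppm", "raw_count", "confident"],
    )
    df.to_csv(path, sep="\t", index=False)


def tss_records_from_frame(df: pd.DataFrame) -> list[TssRecord]:
    """Build TssRecords from an in-memory frame with the table's columns."""
    return [
        TssRecord(
            gene_id=row.gene_id,
            library_id=row.library_id,
            chrom=row.chrom,
            strand=row.strand,
            position=int(row.position),
            expression_ppm=float(row.expression_ppm),
            confident=bool(getattr(row, "confident", True)),
        )
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Region masks (BED)
# ---------------------------------------------------------------------------

def read_region_mask(path: str | Path, label: str = "") -> RegionMask:
    mask = RegionMask(label=label)
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >= 3 BED columns")
            try:
                mask.add(parts[0], int(parts[1]), int(parts[2]))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return mask


def write_region_mask(mask: RegionMask, path: str | Path) -> None:
    with _open(path, "wt") as fh:
        for chrom, start, end in mask.intervals():
            name = mask.label or "."
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


# ---------------------------------------------------------------------------
# JASPAR PFMs
# ---------------------------------------------------------------------------

def read_pfm(path: str | Path) -> list[Pfm]:
    """Read motifs from a JASPAR-format PFM file (A/C/G/T row order)."""
    with _open(path) as fh:
        parsed = motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        out.append(Pfm(motif_id=m.matrix_id or m.name, tf_name=m.name or "", counts=counts))
    return out


def write_pfm(pfms: Iterable[Pfm], path: str | Path) -> None:
    with _open(path, "wt") as fh:
        for p in pfms:
            fh.write(f">{p.motif_id}\t{p.tf_name}\n")
            for base, row in zip("ACGT", p.counts):
                vals = " ".join(f"{v:.2f}".rstrip("0").rstrip(".") for v in row)
                fh.write(f"{base}  [ {vals} ]\n")


# ---------------------------------------------------------------------------
# Allele counts, FASTA, generic tables
# ---------------------------------------------------------------------------

def read_allele_counts(path: str | Path) -> list[AlleleCount]:
    """Read a VCF-derived per-SNP allele count table (tab-separated)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ALLELE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing allele-count columns {missing}")
    return [
        AlleleCount(
            gene_id=r.gene_id,
            library_id=r.library_id,
            chrom=r.chrom,
            pos=int(r.pos),
            ref_count=int(r.ref_count),
            alt_count=int(r.alt_count),
        )
        for r in df.itertuples(index=False)
    ]


def write_allele_counts(counts: Iterable[AlleleCount], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "pos": c.pos,
                "gene_id": c.gene_id,
                "library_id": c.library_id,
                "ref_count": c.ref_count,
                "alt_count": c.alt_count,
            }
            for c in counts
        ]
    ).to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    with _open(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with _open(path, "wt") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_table(path: str | Path, key: str | None = None) -> pd.DataFrame:
    """Generic keyed tab-separated table (expression, DE results, TF lists)."""
    df = pd.read_csv(path, sep="\t")
    if key is not None:
        if key not in df.columns:
            raise ParseError(f"{path}: missing key column {key!r}")
        df = df.set_index(key)
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_gene_list(path: str | Path) -> set[str]:
    """Plain-text identifier list, one per line (used for TF lists)."""
    with _open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}


def write_gene_list(ids: Iterable[str], path: str | Path) -> None:
    with _open(path, "wt") as fh:
        for gid in sorted(ids):
            fh.write(gid + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT reference gene sets: name, description, members (tab-separated)."""
    sets: dict[str, set[str]] = {}
    with _open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, Iterable[str]], path: str | Path) -> None:
    with _open(path, "wt") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "."] + sorted(members)) + "\n")
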