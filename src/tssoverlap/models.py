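"""Core domain types shared across the pipeline.

All genomic coordinates in this package are 0-based, half-open
(``[start, end)``), the BED convention.  Format readers in
:mod:`tssoverlap.io` convert 1-based inclusive inputs (GFF3) at the
boundary; no other module ever shifts a coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from intervaltree import IntervalTree

STRANDS = ("+", "-")
ALPHABET = "ACGT"


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware genomic span of a protein-coding gene.

    ``annotated_five_prime`` is the annotated transcription start
    position: ``span_start`` on the plus strand, ``span_end - 1`` on the
    minus strand (0-based).
    """

    gene_id: str
    chrom: str
    strand: str
    span_start: int
    span_end: int
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        if not self.span_start < self.span_end:
            raise ValueError(
                f"empty span [{self.span_start}, {self.span_end}) for {self.gene_id}"
            )

    @property
    def annotated_five_prime(self) -> int:
        return self.span_start if self.strand == "+" else self.span_end - 1

    @property
    def three_prime_boundary(self) -> int:
        """Annotated 3' end (0-based position of the last transcribed base)."""
        return self.span_end - 1 if self.strand == "+" else self.span_start


@dataclass(frozen=True)
class TssRecord:
    """One observed transcription start site for one gene in one library."""

    gene_id: str
    library_id: str
    chrom: str
    strand: str
    position: int
    expression_ppm: float
    raw_count: int | None = None
    confident: bool = True

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")
        if self.expression_ppm < 0:
            raise ValueError("expression_ppm must be nonnegative")
        if self.raw_count is not None and self.raw_count < 0:
            raise ValueError("raw_count must be nonnegative")


class RegionMask:
    """Labelled set of genomic intervals queryable for point membership.

    Intervals are 0-based half-open; ``(chr1, 100, 200)`` contains
    position 199 but not 200.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = (), label: str = "") -> None:
        self.label = label
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0
        for chrom, start, end in intervals:
            self.add(chrom, start, end)

    def add(self, chrom: str, start: int, end: int) -> None:
        if not start < end:
            raise ValueError(f"invalid interval [{start}, {end})")
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end)
        self._n += 1

    def __len__(self) -> int:
        return self._n

    def contains(self, chrom: str, pos: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos))

    def overlaps_span(self, chrom: str, start: int, end: int) -> bool:
        """True if any masked interval intersects ``[start, end)``."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom, tree in sorted(self._trees.items()):
            out.extend((chrom, iv.begin, iv.end) for iv in sorted(tree))
        return out


@dataclass
class Pfm:
    """Position frequency matrix over ACGT (rows) for one motif."""

    motif_id: str
    tf_name: str
    counts: np.ndarray  # shape (4, L)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4 or self.counts.shape[1] < 1:
            raise ValueError("PFM must be a 4 x L matrix with L >= 1")
        if np.any(self.counts < 0):
            raise ValueError("PFM counts must be nonnegative")
        if np.any(self.counts.sum(axis=0) <= 0):
            raise ValueError("every PFM column needs at least one positive count")

    @property
    def length(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class AlleleCount:
    """Reference/alternative read counts at one heterozygous SNP."""

    gene_id: str
    library_id: str
    chrom: str
    pos: int
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("allele counts must be nonnegative")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count


@dataclass
class GenePair:
    """A candidate head-to-head pair: one gene per strand, same chromosome."""

    pair_id: str
    gene_plus: str
    gene_minus: str
    chrom: str


@dataclass
class PairLibraryStatus:
    """Overlap verdict for one pair in one library.

    ``state`` is one of ``overlap``, ``no_overlap``, ``single_expressed``,
    ``none_expressed``.  ``tss_class_*`` is ``absent``, ``single`` or
    ``multiple``.  ``fraction_overlapping_*`` is the fraction of a gene's
    TSS expression (ppm) initiated inside the overlap region; NaN when
    undefined (gene unexpressed or pair not overlapping).
    """

    pair_id: str
    library_id: str
    state: str
    overlap_len_bp: int = 0
    tss_class_plus: str = "absent"
    tss_class_minus: str = "absent"
    fraction_overlapping_plus: float = float("nan")
    fraction_overlapping_minus: float = float("nan")
    five_prime_plus: int | None = None
    five_prime_minus: int | None = None


@dataclass
class AseCall:
    """Allele-specific-expression classification for one gene."""

    gene_id: str
    per_library: dict[str, str] = field(default_factory=dict)
    overall: str = "noninformative"
    n_snps_used: int = 0
    excluded_reason: str | None = None
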