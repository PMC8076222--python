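"""Per-library 5'-overlap calling for head-to-head gene pairs.

A pair's status in a library is decided entirely by the *most upstream*
admitted TSS of each gene (its effective 5' end) and by the annotated
3' boundaries.  With ``a`` the plus gene's effective 5' end and ``b``
the minus gene's, the per-library gene extents are ``{a .. plus 3'}``
and ``{minus 3' .. b}`` (inclusive base sets); the pair overlaps when
both genes are expressed, ``b >= a``, and each effective 5' end lies
inside the partner's extent.  The shared span is then ``[a, b]`` with
length ``b - a + 1`` — at least one base by construction.

The "5' end inside the partner's extent" condition restricts calls to
genuine head-to-head 5' overlaps, excluding nested or tandem
geometries; it is configurable off for exploratory use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .models import GeneModel, GenePair, PairLibraryStatus, TssRecord

DEFAULT_MAX_GAP_BP = 10_000

PAIR_STATES = ("overlap", "no_overlap", "single_expressed", "none_expressed")
SIX_CATEGORIES = (
    "overlap_single",
    "overlap_multi",
    "no_overlap_single",
    "no_overlap_multi",
    "single_expressed_single",
    "single_expressed_multi",
)


def effective_five_prime(gene: GeneModel, tss_records: Sequence[TssRecord]) -> int | None:
    """Most upstream admitted TSS of ``gene`` in one library, or None.

    Upstream means the minimum position on the plus strand and the
    maximum on the minus strand.
    """
    positions = [r.position for r in tss_records]
    for r in tss_records:
        if r.gene_id != gene.gene_id:
            raise ValueError(f"TSS record for {r.gene_id} passed with gene {gene.gene_id}")
    if not positions:
        return None
    return min(positions) if gene.strand == "+" else max(positions)


def candidate_pairs(
    genes: Iterable[GeneModel], max_gap_bp: int = DEFAULT_MAX_GAP_BP
) -> list[GenePair]:
    """Enumerate every same-chromosome opposite-strand pair that could
    5'-overlap under any admitted TSS choice.

    A gene's possible per-library extent is its annotated span extended
    on the 5' side by up to ``max_gap_bp`` (the TSS search radius is at
    most half of this under the default filter).  Two genes are
    candidates when those extended extents intersect — a superset of
    every configuration an exhaustive overlap scan could call
    overlapping.  Each unordered pair is listed once, plus gene first.
    """
    plus = [g for g in genes if g.strand == "+"]
    minus_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        if g.strand == "-":
            minus_by_chrom.setdefault(g.chrom, []).append(g)

    trees: dict[str, IntervalTree] = {}
    minus_index: dict[str, list[GeneModel]] = {}
    for chrom, gs in minus_by_chrom.items():
        tree = IntervalTree()
        for i, g in enumerate(gs):
            # minus gene possible extent: [span_start, five' + gap]
            tree.addi(g.span_start, g.annotated_five_prime + max_gap_bp + 1, i)
        trees[chrom] = tree
        minus_index[chrom] = gs

    pairs: list[GenePair] = []
    for g in plus:
        tree = trees.get(g.chrom)
        if tree is None:
            continue
        # plus gene possible extent: [five' - gap, span_end)
        lo = g.annotated_five_prime - max_gap_bp
        for hit in sorted(tree.overlap(lo, g.span_end), key=lambda iv: iv.data):
            m = minus_index[g.chrom][hit.data]
            pairs.append(
                GenePair(
                    pair_id=f"{g.gene_id}|{m.gene_id}",
                    gene_plus=g.gene_id,
                    gene_minus=m.gene_id,
                    chrom=g.chrom,
                )
            )
    return pairs


def _tss_class(n: int) -> str:
    if n == 0:
        return "absent"
    return "single" if n == 1 else "multiple"


def call_overlap(
    pair: GenePair,
    library_id: str,
    genes: Mapping[str, GeneModel],
    tss_plus: Sequence[TssRecord],
    tss_minus: Sequence[TssRecord],
    require_head_to_head: bool = True,
) -> PairLibraryStatus:
    """Overlap verdict for one pair in one library.

    ``tss_plus`` / ``tss_minus`` are the admitted TSS records of the
    pair's genes in this library (may be empty).
    """
    gp, gm = genes[pair.gene_plus], genes[pair.gene_minus]
    if gp.chrom != gm.chrom:
        raise ValueError(f"pair {pair.pair_id}: genes on different chromosomes")
    if gp.strand != "+" or gm.strand != "-":
        raise ValueError(f"pair {pair.pair_id}: expected (+,-) strand orientation")

    a = effective_five_prime(gp, tss_plus)
    b = effective_five_prime(gm, tss_minus)
    pos_plus = sorted({r.position for r in tss_plus})
    pos_minus = sorted({r.position for r in tss_minus})

    status = PairLibraryStatus(
        pair_id=pair.pair_id,
        library_id=library_id,
        state="none_expressed",
        tss_class_plus=_tss_class(len(pos_plus)),
        tss_class_minus=_tss_class(len(pos_minus)),
        five_prime_plus=a,
        five_prime_minus=b,
    )
    if a is None and b is None:
        return status
    if a is None or b is None:
        status.state = "single_expressed"
        return status

    # inclusive per-library extents: plus {a .. span_end-1}, minus {span_start .. b}
    is_overlap = b >= a
    if require_head_to_head:
        is_overlap = is_overlap and (gm.span_start <= a) and (b <= gp.span_end - 1)
    if is_overlap:
        status.state = "overlap"
        status.overlap_len_bp = b - a + 1
        status.fraction_overlapping_plus = _fraction_in(tss_plus, a, b)
        status.fraction_overlapping_minus = _fraction_in(tss_minus, a, b)
    else:
        status.state = "no_overlap"
    return status


def _fraction_in(records: Sequence[TssRecord], lo: int, hi: int) -> float:
    total = sum(r.expression_ppm for r in records)
    if total <= 0:
        return float("nan")
    inside = sum(r.expression_ppm for r in records if lo <= r.position <= hi)
    return inside / total


def call_all(
    pairs: Sequence[GenePair],
    genes: Mapping[str, GeneModel] | Iterable[GeneModel],
    admitted: Sequence[TssRecord],
    libraries: Sequence[str] | None = None,
    require_head_to_head: bool = True,
) -> list[PairLibraryStatus]:
    """Call every (pair, library) combination from admitted TSS records."""
    if not isinstance(genes, Mapping):
        genes = {g.gene_id: g for g in genes}
    if libraries is None:
        libraries = sorted({r.library_id for r in admitted})
    by_gene_lib: dict[tuple[str, str], list[TssRecord]] = {}
    for r in admitted:
        by_gene_lib.setdefault((r.gene_id, r.library_id), []).append(r)
    out = []
    for pair in pairs:
        for lib in libraries:
            out.append(
                call_overlap(
                    pair,
                    lib,
                    genes,
                    by_gene_lib.get((pair.gene_plus, lib), ()),
                    by_gene_lib.get((pair.gene_minus, lib), ()),
                    require_head_to_head=require_head_to_head,
                )
            )
    return out


@dataclass
class PairSummary:
    """Per-pair and per-library tallies over all statuses."""

    per_pair: pd.DataFrame  # index pair_id; n_libraries_both_expressed, n_libraries_overlap
    always_overlap: list[str]  # pairs overlapping in every co-expressed library
    per_library: pd.DataFrame  # index library_id; n_pairs_overlap


def pair_library_summary(statuses: Sequence[PairLibraryStatus]) -> PairSummary:
    """Tallies behind the expressed-vs-overlapping library counts.

    A library counts as "both expressed" when the state is overlap or
    no_overlap.  The always-overlap subset contains pairs overlapping
    in *every* library where both genes are expressed (and at least
    one such library exists).
    """
    df = pd.DataFrame(
        {
            "pair_id": [s.pair_id for s in statuses],
            "library_id": [s.library_id for s in statuses],
            "state": [s.state for s in statuses],
        }
    )
    both = df["state"].isin(["overlap", "no_overlap"])
    over = df["state"] == "overlap"
    per_pair = pd.DataFrame(
        {
            "n_libraries_both_expressed": both.groupby(df["pair_id"]).sum(),
            "n_libraries_overlap": over.groupby(df["pair_id"]).sum(),
        }
    )
    always = per_pair[
        (per_pair["n_libraries_overlap"] == per_pair["n_libraries_both_expressed"])
        & (per_pair["n_libraries_both_expressed"] >= 1)
    ].index.tolist()
    per_library = (
        over.groupby(df["library_id"]).sum().rename("n_pairs_overlap").to_frame()
    )
    return PairSummary(per_pair=per_pair, always_overlap=always, per_library=per_library)


def six_category(state: str, n_tss: int) -> str | None:
    """Six-way organization x TSS-count category for one expressed gene.

    ``state`` is the pair state in the library; ``n_tss`` the number of
    distinct admitted TSSs the classified gene uses there.  Genes in a
    none_expressed pair (or with no TSS) take no category.
    """
    if state == "none_expressed" or n_tss == 0:
        return None
    if state not in PAIR_STATES:
        raise ValueError(f"unknown state {state!r}")
    axis = "single" if n_tss == 1 else "multi"
    return f"{state}_{axis}"


def gene_category_frame(statuses: Sequence[PairLibraryStatus], tss_counts: Mapping) -> pd.DataFrame:
    """Per (gene, library) six-way categories for every expressed gene.

    ``tss_counts`` maps (gene_id, library_id) to the distinct admitted
    TSS count (see :func:`tssoverlap.tss_filter.tss_count_per_gene_library`).
    A gene appearing in several pairs is classified once per pair
    occurrence; each expressed gene-library observation lands in
    exactly one of the six categories.
    """
    rows = []
    for s in statuses:
        pair_plus, pair_minus = s.pair_id.split("|")
        for gene_id, cls in ((pair_plus, s.tss_class_plus), (pair_minus, s.tss_class_minus)):
            if cls == "absent":
                continue
            n = int(tss_counts.get((gene_id, s.library_id), 0))
            cat = six_category(s.state, n)
            if cat is not None:
                rows.append(
                    {
                        "gene_id": gene_id,
                        "library_id": s.library_id,
                        "pair_id": s.pair_id,
                        "category": cat,
                    }
                )
    return pd.DataFrame(rows, columns=["gene_id", "library_id", "pair_id", "category"])


def statuses_to_frame(statuses: Sequence[PairLibraryStatus]) -> pd.DataFrame:
    """Long-format status table (the call-overlap TSV)."""
    return pd.DataFrame(
        [
            {
                "pair_id": s.pair_id,
                "library_id": s.library_id,
                "state": s.state,
                "overlap_len_bp": s.overlap_len_bp,
                "tss_class_plus": s.tss_class_plus,
                "tss_class_minus": s.tss_class_minus,
                "fraction_overlapping_plus": s.fraction_overlapping_plus,
                "fraction_overlapping_minus": s.fraction_overlapping_minus,
                "five_prime_plus": s.five_prime_plus,
                "five_prime_minus": s.five_prime_minus,
            }
            for s in statuses
        ]
    )


def statuses_from_frame(df: pd.DataFrame) -> list[PairLibraryStatus]:
    out = []
    for r in df.itertuples(index=False):
        out.append(
            PairLibraryStatus(
                pair_id=r.pair_id,
                library_id=r.library_id,
                state=r.state,
                overlap_len_bp=int(r.overlap_len_bp),
                tss_class_plus=r.tss_class_plus,
                tss_class_minus=r.tss_class_minus,
                fraction_overlapping_plus=float(r.fraction_overlapping_plus),
                fraction_overlapping_minus=float(r.fraction_overlapping_minus),
                five_prime_plus=None if pd.isna(r.five_prime_plus) else int(r.five_prime_plus),
                five_prime_minus=None if pd.isna(r.five_prime_minus) else int(r.five_prime_minus),
            )
        )
    return out
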