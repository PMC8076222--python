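"""Condition-dependent promoter switches and TF association.

A pair "switches" between a control and a treated condition when it is
not overlapping in *every* control library and overlapping in *every*
treated library.  The genes responsible are those whose effective 5'
end (most upstream admitted TSS) moved between conditions; the shift is
strand-aware (positive = upstream: smaller coordinate on +, larger on
-).  A switch can add a new upstream TSS while keeping the old one
(``new_tss_is_additional``).

Differential-expression results are consumed, not fitted: a gene is up
when log2FC > 1.5 and FDR < 0.05 (both strict), down when
log2FC < -1.5 and FDR < 0.05.  A TF associates with a TSS when one of
its motif hits lies within 500 bp of it (inclusive, hit-midpoint
anchor, symmetric); a TSS-specific TF associates with exactly one of a
gene's TSSs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .models import GeneModel, PairLibraryStatus, TssRecord
from .motif import MotifHit

DEFAULT_LFC_MIN = 1.5
DEFAULT_FDR_MAX = 0.05
DEFAULT_WINDOW_BP = 500

NONOVERLAP_STATES = {"no_overlap", "single_expressed", "none_expressed"}


@dataclass
class SwitchEvent:
    pair_id: str
    control_libs: set[str]
    treated_libs: set[str]
    switching_genes: list[str] = field(default_factory=list)
    upstream_shift_bp: dict[str, int] = field(default_factory=dict)
    new_tss_is_additional: dict[str, bool] = field(default_factory=dict)


def _condition_five_prime(
    gene: GeneModel, records: Sequence[TssRecord], libs: set[str]
) -> int | None:
    """Most upstream admitted TSS of a gene across a condition's libraries."""
    positions = [r.position for r in records if r.library_id in libs]
    if not positions:
        return None
    return min(positions) if gene.strand == "+" else max(positions)


def detect_switches(
    statuses: Sequence[PairLibraryStatus],
    genes: Mapping[str, GeneModel],
    admitted: Sequence[TssRecord],
    control_libs: Iterable[str],
    treated_libs: Iterable[str],
) -> list[SwitchEvent]:
    """Pairs nonoverlapping in all controls and overlapping in all treated.

    ``admitted`` are the filtered TSS records, used to determine which
    gene(s) moved their effective 5' end and whether the control TSS is
    still used after treatment.
    """
    control, treated = set(control_libs), set(treated_libs)
    if not control or not treated:
        raise ValueError("both library sets must be nonempty")
    if control & treated:
        raise ValueError("control and treated library sets must be disjoint")

    by_pair: dict[str, dict[str, str]] = {}
    for s in statuses:
        by_pair.setdefault(s.pair_id, {})[s.library_id] = s.state

    by_gene: dict[str, list[TssRecord]] = {}
    for r in admitted:
        by_gene.setdefault(r.gene_id, []).append(r)

    events = []
    for pair_id in sorted(by_pair):
        states = by_pair[pair_id]
        if any(lib not in states for lib in control | treated):
            continue
        if not all(states[lib] in NONOVERLAP_STATES for lib in control):
            continue
        if not all(states[lib] == "overlap" for lib in treated):
            continue
        event = SwitchEvent(pair_id=pair_id, control_libs=control, treated_libs=treated)
        for gene_id in pair_id.split("|"):
            gene = genes[gene_id]
            recs = by_gene.get(gene_id, [])
            ctrl_pos = _condition_five_prime(gene, recs, control)
            trt_pos = _condition_five_prime(gene, recs, treated)
            if trt_pos is None or trt_pos == ctrl_pos:
                continue
            event.switching_genes.append(gene_id)
            if ctrl_pos is None:
                shift = 0
            elif gene.strand == "+":
                shift = ctrl_pos - trt_pos  # upstream = smaller coordinate
            else:
                shift = trt_pos - ctrl_pos  # upstream = larger coordinate
            event.upstream_shift_bp[gene_id] = shift
            treated_positions = {r.position for r in recs if r.library_id in treated}
            event.new_tss_is_additional[gene_id] = (
                ctrl_pos is not None and ctrl_pos in treated_positions
            )
        events.append(event)
    return events


def apply_de_thresholds(
    de_table: pd.DataFrame,
    lfc_min: float = DEFAULT_LFC_MIN,
    fdr_max: float = DEFAULT_FDR_MAX,
) -> tuple[set[str], set[str]]:
    """Up/down gene sets under strict log2FC and FDR thresholds.

    ``de_table`` needs columns ``gene_id``, ``log2fc``, ``fdr``.
    """
    sig = de_table["fdr"] < fdr_max
    up = set(de_table.loc[sig & (de_table["log2fc"] > lfc_min), "gene_id"])
    down = set(de_table.loc[sig & (de_table["log2fc"] < -lfc_min), "gene_id"])
    return up, down


def intersect_tf(
    up: Iterable[str], down: Iterable[str], tf_ids: Iterable[str]
) -> tuple[set[str], set[str]]:
    """Restrict DE gene sets to known transcription factors."""
    tfs = set(tf_ids)
    return set(up) & tfs, set(down) & tfs


@dataclass
class TssTfAssociation:
    gene_id: str
    per_tss: dict[int, set[str]]  # TSS position -> associated TF motif ids
    tss_specific: dict[str, int]  # motif id -> the single TSS it associates with


def associate_tss_tfbs(
    gene_id: str,
    tss_positions: Iterable[int],
    hits: Sequence[MotifHit],
    motif_lengths: Mapping[str, int],
    window_bp: int = DEFAULT_WINDOW_BP,
) -> TssTfAssociation:
    """Associate motif hits with each of a gene's TSSs.

    A hit associates with a TSS when its midpoint lies within
    ``window_bp`` of the TSS (inclusive, both directions).  TSS-specific
    motifs associate with exactly one of the gene's TSSs.
    """
    positions = sorted(set(tss_positions))
    per_tss: dict[int, set[str]] = {p: set() for p in positions}
    for h in hits:
        L = motif_lengths[h.motif_id]
        midpoint = h.start + (L - 1) // 2
        for p in positions:
            if abs(midpoint - p) <= window_bp:
                per_tss[p].add(h.motif_id)
    specific = {}
    for motif_id in {m for tfs in per_tss.values() for m in tfs}:
        assoc = [p for p, tfs in per_tss.items() if motif_id in tfs]
        if len(assoc) == 1:
            specific[motif_id] = assoc[0]
    return TssTfAssociation(gene_id=gene_id, per_tss=per_tss, tss_specific=specific)


def events_to_frame(events: Sequence[SwitchEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append(
            {
                "pair_id": e.pair_id,
                "switching_genes": ";".join(e.switching_genes),
                "upstream_shift_bp": ";".join(
                    f"{g}={e.upstream_shift_bp[g]}" for g in e.switching_genes if g in e.upstream_shift_bp
                ),
                "new_tss_is_additional": ";".join(
                    f"{g}={e.new_tss_is_additional[g]}"
                    for g in e.switching_genes
                    if g in e.new_tss_is_additional
                ),
            }
        )
    return pd.DataFrame(rows, columns=["pair_id", "switching_genes", "upstream_shift_bp", "new_tss_is_additional"])
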