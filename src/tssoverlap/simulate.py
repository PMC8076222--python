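"""Synthetic data with planted ground truth for every pipeline stage.

The generator lays out head-to-head gene pairs on a linear chromosome.
Each pair is built around a center ``c``: the plus-strand gene's
*overlapping* TSS sits at ``c - overlap_half`` and the minus-strand
gene's at ``c + overlap_half``, so the pair shares ``2*overlap_half + 1``
bases exactly when both genes initiate from those TSSs.  Each gene also
owns a *non-overlapping* TSS ``switch_tss_offset`` bases downstream (on
its own strand), far enough from the overlapping one that a 500 bp
motif window around one TSS cannot reach the other.

Per library, the pair overlaps with the propensity of the library's
group when the pair belongs to that group, and with a common
cross-group propensity otherwise — the block structure hierarchical
clustering is expected to recover.  Expression is log-normal with a
configurable uplift in libraries where the gene's pair overlaps and a
between-gene correlation induced by a shared latent factor.  Allele
counts are binomial draws around planted minor-allele fractions that
straddle the 2% and 20% classification thresholds.  Switch pairs use
non-overlapping TSSs in every control library and overlapping ones in
every treated library; a strong consensus motif for a planted
up-regulated TF is written into the promoter sequence near the newly
activated TSS only.

Everything the generator knows is recorded in a :class:`TruthRecord`
so recovery can be scored mechanically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as tio
from .models import AlleleCount, GeneModel, Pfm, RegionMask, TssRecord

# planted minor-allele fractions per ASE class: well inside the
# < 2% / 2-20% / >= 20% classification bands
ASE_CLASS_FRACTIONS = {"monoallelic": 0.005, "skewed": 0.10, "biallelic": 0.45}

ACT_CONSENSUS = "AGGTCATGCC"  # planted activator motif (up-regulated TF)
REP_CONSENSUS = "CCAATTGGCG"  # planted repressor motif (down-regulated TF)
BG_CONSENSUS = "CATGGCCATT"  # background motif, TF not differentially expressed


@dataclass
class LibraryGroup:
    label: str
    size: int
    overlap_propensity: float


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe the standard scenario: 200 pairs in three
    equally-sized groups of 10 libraries each, within-group overlap
    propensity 0.9 against 0.4 elsewhere, a 0.5 log2-unit expression
    uplift in overlap libraries, and a transfection-style switch
    scenario with 2 control and 4 treated libraries.
    """

    seed: int = 0
    n_pairs: int = 200
    n_constitutive_pairs: int = 5
    n_switch_pairs: int = 5
    n_singleton_genes: int = 30
    library_groups: list[LibraryGroup] = field(
        default_factory=lambda: [
            LibraryGroup("tissue", 10, 0.9),
            LibraryGroup("cellline", 10, 0.9),
            LibraryGroup("cancer", 10, 0.9),
        ]
    )
    cross_propensity: float = 0.4
    p_expressed: float = 0.95
    p_extra_tss: float = 0.35
    # geometry (bp)
    locus_spacing: int = 50_000
    gene_length: int = 8_000
    overlap_half: int = 25
    switch_tss_offset: int = 1_200
    extra_tss_step: int = 400
    # TSS expression (ppm) above the admission threshold
    tss_ppm_floor: float = 5.0
    # noise records exercising the admission rules, per library
    n_noise_low_ppm: int = 3
    n_noise_nonconfident: int = 3
    n_noise_distant: int = 3
    # gene expression model (log2 scale)
    expr_baseline_mean: float = 4.0
    expr_baseline_sd: float = 1.5
    expr_sigma: float = 1.0
    overlap_uplift: float = 0.5
    pair_rho: float = 0.5
    # allele-specific expression
    ase_class_probs: dict = field(
        default_factory=lambda: {
            "monoallelic": 0.1,
            "skewed": 0.1,
            "biallelic": 0.6,
            "mixed": 0.2,
        }
    )
    n_ase_libraries: int = 4
    n_snps_per_gene: tuple = (2, 4)
    depth_floor: int = 30
    depth_mean: float = 60.0
    n_overlap_region_snps: int = 4  # planted inside overlap spans (should be excluded)
    n_low_depth_snps: int = 4  # planted below min depth (should be excluded)
    n_nondiploid_singletons: int = 2
    # switch scenario
    n_control_libs: int = 2
    n_treated_libs: int = 4
    # motif planting
    motif_counts_total: int = 1000

    def library_ids(self) -> list[str]:
        libs = []
        for g in self.library_groups:
            libs.extend(f"{g.label}_{i + 1}" for i in range(g.size))
        return libs

    def control_library_ids(self) -> list[str]:
        return [f"ctrl_{i + 1}" for i in range(self.n_control_libs)]

    def treated_library_ids(self) -> list[str]:
        return [f"trt_{i + 1}" for i in range(self.n_treated_libs)]


@dataclass
class TruthRecord:
    """Everything the generator planted, keyed by entity id."""

    pair_group: dict[str, str] = field(default_factory=dict)
    library_group: dict[str, str] = field(default_factory=dict)
    pair_states: dict = field(default_factory=dict)  # (pair_id, lib) -> state
    constitutive_pairs: list[str] = field(default_factory=list)
    switch_pairs: dict = field(default_factory=dict)  # pair -> switch info
    gene_ase_class: dict[str, str] = field(default_factory=dict)
    gene_library_ase_class: dict = field(default_factory=dict)  # (gene, lib) -> class
    snp_class: dict = field(default_factory=dict)  # (gene, lib, chrom, pos) -> class
    excluded_snps: dict = field(default_factory=dict)  # same key -> reason
    nondiploid_genes: list[str] = field(default_factory=list)
    noise_tss: dict = field(default_factory=dict)  # index in tss list -> reason
    motif_plants: list[dict] = field(default_factory=list)
    de_up: list[str] = field(default_factory=list)
    de_down: list[str] = field(default_factory=list)
    pair_rho: float = 0.0


@dataclass
class SimBundle:
    config: SimConfig
    genes: list[GeneModel]
    tss_records: list[TssRecord]
    expression: pd.DataFrame  # genes x libraries
    allele_counts: list[AlleleCount]
    nondiploid_mask: RegionMask
    de_table: pd.DataFrame
    tf_ids: set[str]
    pfms: list[Pfm]
    promoters: dict[str, str]
    promoter_offsets: dict[str, int]
    truth: TruthRecord

    @property
    def pair_ids(self) -> list[str]:
        return sorted(self.truth.pair_group)

    @property
    def all_library_ids(self) -> list[str]:
        cfg = self.config
        return cfg.library_ids() + cfg.control_library_ids() + cfg.treated_library_ids()


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _consensus_pfm(motif_id: str, tf_name: str, consensus: str, total: int) -> Pfm:
    counts = np.full((4, len(consensus)), 1.0)
    for j, base in enumerate(consensus):
        counts["ACGT".index(base), j] = total - 3
    return Pfm(motif_id=motif_id, tf_name=tf_name, counts=counts)


def _pair_geometry(cfg: SimConfig, index: int) -> dict:
    c = index * cfg.locus_spacing + 10_000
    return {
        "center": c,
        "plus_ov": c - cfg.overlap_half,
        "plus_no": c + cfg.switch_tss_offset,
        "minus_ov": c + cfg.overlap_half,
        "minus_no": c - cfg.switch_tss_offset,
        "plus_span": (c - cfg.overlap_half, c - cfg.overlap_half + cfg.gene_length),
        "minus_span": (
            c + cfg.overlap_half - cfg.gene_length + 1,
            c + cfg.overlap_half + 1,
        ),
    }


def generate(config: SimConfig | None = None, seed: int | None = None) -> SimBundle:
    """Generate the full synthetic cohort; deterministic under the seed."""
    cfg = config or SimConfig()
    if seed is not None:
        cfg = SimConfig(**{**cfg.__dict__, "seed": seed})
    if cfg.overlap_half < 0 or cfg.switch_tss_offset <= cfg.overlap_half:
        raise ValueError("infeasible geometry: switch TSS must be outside the overlap span")
    if cfg.gene_length <= cfg.switch_tss_offset + cfg.overlap_half:
        raise ValueError("infeasible geometry: gene too short for its TSSs")
    rng = np.random.default_rng(cfg.seed)
    truth = TruthRecord(pair_rho=cfg.pair_rho)

    group_labels = [g.label for g in cfg.library_groups]
    group_of_lib: dict[str, str] = {}
    propensity_of_group = {g.label: g.overlap_propensity for g in cfg.library_groups}
    for g in cfg.library_groups:
        for i in range(g.size):
            group_of_lib[f"{g.label}_{i + 1}"] = g.label
    truth.library_group = dict(group_of_lib)
    group_libs = cfg.library_ids()
    ctrl_libs = cfg.control_library_ids()
    trt_libs = cfg.treated_library_ids()

    # --- genes ------------------------------------------------------------
    genes: list[GeneModel] = []
    geometries: dict[str, dict] = {}
    pair_kind: dict[str, str] = {}  # regular / constitutive / switch

    def add_pair(pid: str, idx: int, kind: str, group: str) -> None:
        geo = _pair_geometry(cfg, idx)
        gp = GeneModel(f"{pid}P", "chr1", "+", *geo["plus_span"])
        gm = GeneModel(f"{pid}M", "chr1", "-", *geo["minus_span"])
        genes.extend([gp, gm])
        pair_id = f"{gp.gene_id}|{gm.gene_id}"
        geometries[pair_id] = geo
        pair_kind[pair_id] = kind
        truth.pair_group[pair_id] = group

    idx = 0
    for i in range(cfg.n_pairs):
        add_pair(f"PR{i:04d}", idx, "regular", group_labels[i % len(group_labels)])
        idx += 1
    for i in range(cfg.n_constitutive_pairs):
        add_pair(f"CO{i:04d}", idx, "constitutive", "constitutive")
        idx += 1
    for i in range(cfg.n_switch_pairs):
        add_pair(f"SW{i:04d}", idx, "switch", group_labels[i % len(group_labels)])
        idx += 1
    truth.constitutive_pairs = sorted(p for p, k in pair_kind.items() if k == "constitutive")

    singleton_ids = []
    for i in range(cfg.n_singleton_genes):
        start = i * cfg.locus_spacing + 10_000
        strand = "+" if i % 2 == 0 else "-"
        g = GeneModel(f"SG{i:04d}", "chr2", strand, start, start + cfg.gene_length)
        genes.append(g)
        singleton_ids.append(g.gene_id)

    gene_index = {g.gene_id: g for g in genes}

    # --- per-library TSS usage and pair states ----------------------------
    tss_rows: list[TssRecord] = []
    overlap_state: dict = {}  # (gene_id, lib) -> bool pair-overlap (for uplift)
    expressed: dict = {}  # (gene_id, lib) -> bool

    def tss_ppm() -> float:
        return round(cfg.tss_ppm_floor + rng.gamma(2.0, 10.0), 3)

    def emit_tss(gene: GeneModel, lib: str, positions: Sequence[int]) -> None:
        for pos in positions:
            tss_rows.append(
                TssRecord(
                    gene_id=gene.gene_id,
                    library_id=lib,
                    chrom=gene.chrom,
                    strand=gene.strand,
                    position=int(pos),
                    expression_ppm=tss_ppm(),
                    confident=True,
                )
            )

    def gene_positions(pair_id: str, side: str, use_ov: bool, extra: bool) -> list[int]:
        geo = geometries[pair_id]
        ov = geo[f"{side}_ov"]
        no = geo[f"{side}_no"]
        positions = [ov] if use_ov else [no]
        if extra:
            step = cfg.extra_tss_step if side == "plus" else -cfg.extra_tss_step
            positions.append(no + step)
        return positions

    # the six switch-scenario libraries behave identically within a pair:
    # replicate cell-line conditions use a consistent TSS choice, which also
    # keeps the planted switch pairs the only condition-consistent switches
    for pair_id, kind in pair_kind.items():
        gp_id, gm_id = pair_id.split("|")
        pgroup = truth.pair_group[pair_id]
        for lib in group_libs:
            ep = rng.random() < cfg.p_expressed
            em = rng.random() < cfg.p_expressed
            expressed[(gp_id, lib)] = ep
            expressed[(gm_id, lib)] = em
            if not ep and not em:
                truth.pair_states[(pair_id, lib)] = "none_expressed"
                continue
            if ep != em:
                truth.pair_states[(pair_id, lib)] = "single_expressed"
                side = "plus" if ep else "minus"
                gid = gp_id if ep else gm_id
                use_ov = bool(rng.random() < 0.5)
                emit_tss(
                    gene_index[gid],
                    lib,
                    gene_positions(pair_id, side, use_ov, rng.random() < cfg.p_extra_tss),
                )
                continue
            if kind == "constitutive":
                p_overlap = 1.0
            elif group_of_lib[lib] == pgroup:
                p_overlap = propensity_of_group[group_of_lib[lib]]
            else:
                p_overlap = cfg.cross_propensity
            is_overlap = rng.random() < p_overlap
            truth.pair_states[(pair_id, lib)] = "overlap" if is_overlap else "no_overlap"
            overlap_state[(gp_id, lib)] = is_overlap
            overlap_state[(gm_id, lib)] = is_overlap
            if is_overlap:
                use_ov_p = use_ov_m = True
            else:
                combo = rng.integers(3)  # forbid (ov, ov)
                use_ov_p = combo == 0
                use_ov_m = combo == 1
            emit_tss(
                gene_index[gp_id],
                lib,
                gene_positions(pair_id, "plus", use_ov_p, rng.random() < cfg.p_extra_tss),
            )
            emit_tss(
                gene_index[gm_id],
                lib,
                gene_positions(pair_id, "minus", use_ov_m, rng.random() < cfg.p_extra_tss),
            )

        # switch-scenario libraries
        if kind == "switch":
            sw_index = sorted(p for p, k in pair_kind.items() if k == "switch").index(pair_id)
            # alternate which gene switches; every 3rd pair switches both
            if sw_index % 3 == 2:
                movers = ("plus", "minus")
            elif sw_index % 2 == 0:
                movers = ("plus",)
            else:
                movers = ("minus",)
            additional = sw_index % 2 == 0  # keep the old TSS in treated libs
            info = {"movers": list(movers), "additional": additional, "shifts": {}}
            for side, gid in (("plus", gp_id), ("minus", gm_id)):
                geo = geometries[pair_id]
                info["shifts"][gid] = (
                    cfg.switch_tss_offset + cfg.overlap_half if side in movers else 0
                )
            truth.switch_pairs[pair_id] = info
            for lib in ctrl_libs:
                truth.pair_states[(pair_id, lib)] = "no_overlap"
                expressed[(gp_id, lib)] = expressed[(gm_id, lib)] = True
                # control: movers sit on their non-overlapping TSS; a
                # non-moving partner may already use its overlapping TSS
                emit_tss(gene_index[gp_id], lib, gene_positions(pair_id, "plus", "plus" not in movers, False))
                emit_tss(gene_index[gm_id], lib, gene_positions(pair_id, "minus", "minus" not in movers, False))
            for lib in trt_libs:
                truth.pair_states[(pair_id, lib)] = "overlap"
                expressed[(gp_id, lib)] = expressed[(gm_id, lib)] = True
                overlap_state[(gp_id, lib)] = overlap_state[(gm_id, lib)] = True
                for side, gid in (("plus", gp_id), ("minus", gm_id)):
                    positions = gene_positions(pair_id, side, True, False)
                    if side in movers and additional:
                        positions += gene_positions(pair_id, side, False, False)
                    emit_tss(gene_index[gid], lib, positions)
        else:
            # non-switch pairs: one consistent state across all six
            # condition libraries (drawn once)
            ep = rng.random() < cfg.p_expressed
            if not ep:
                state, use_ov = "none_expressed", False
            else:
                use_ov = bool(rng.random() < cfg.cross_propensity) if kind == "regular" else True
                state = "overlap" if use_ov else "no_overlap"
            for lib in ctrl_libs + trt_libs:
                truth.pair_states[(pair_id, lib)] = state
                expressed[(gp_id, lib)] = expressed[(gm_id, lib)] = ep
                if ep:
                    overlap_state[(gp_id, lib)] = overlap_state[(gm_id, lib)] = use_ov
                    emit_tss(gene_index[gp_id], lib, gene_positions(pair_id, "plus", use_ov, False))
                    emit_tss(gene_index[gm_id], lib, gene_positions(pair_id, "minus", use_ov, False))

    all_libs = group_libs + ctrl_libs + trt_libs
    for gid in singleton_ids:
        g = gene_index[gid]
        for lib in all_libs:
            e = rng.random() < cfg.p_expressed
            expressed[(gid, lib)] = e
            if e:
                n = 1 + int(rng.random() < cfg.p_extra_tss)
                direction = 1 if g.strand == "+" else -1
                positions = [
                    g.annotated_five_prime + direction * k * cfg.extra_tss_step
                    for k in range(n)
                ]
                emit_tss(g, lib, positions)

    # noise records exercising each admission rule (planted rejects)
    noise_genes = [g for g in genes if g.chrom == "chr1"]
    for lib in group_libs:
        for _ in range(cfg.n_noise_low_ppm):
            g = noise_genes[rng.integers(len(noise_genes))]
            tss_rows.append(
                TssRecord(g.gene_id, lib, g.chrom, g.strand, g.annotated_five_prime + 10,
                          round(float(rng.uniform(0.1, 4.99)), 3), None, True)
            )
            truth.noise_tss[len(tss_rows) - 1] = "low_ppm"
        for _ in range(cfg.n_noise_nonconfident):
            g = noise_genes[rng.integers(len(noise_genes))]
            tss_rows.append(
                TssRecord(g.gene_id, lib, g.chrom, g.strand, g.annotated_five_prime + 20,
                          tss_ppm(), None, False)
            )
            truth.noise_tss[len(tss_rows) - 1] = "not_confident"
        for _ in range(cfg.n_noise_distant):
            g = noise_genes[rng.integers(len(noise_genes))]
            direction = 1 if g.strand == "+" else -1
            pos = g.annotated_five_prime + direction * int(rng.integers(5001, 8000))
            tss_rows.append(TssRecord(g.gene_id, lib, g.chrom, g.strand, pos, tss_ppm(), None, True))
            truth.noise_tss[len(tss_rows) - 1] = "too_distant"

    # --- expression table -------------------------------------------------
    baseline = {g.gene_id: rng.normal(cfg.expr_baseline_mean, cfg.expr_baseline_sd) for g in genes}
    expr = pd.DataFrame(0.0, index=[g.gene_id for g in genes], columns=all_libs)
    for pair_id in pair_kind:
        gp_id, gm_id = pair_id.split("|")
        for lib in all_libs:
            z = rng.normal()  # shared latent factor -> Pearson rho between the pair
            for gid in (gp_id, gm_id):
                if not expressed.get((gid, lib), False):
                    continue
                eps = np.sqrt(cfg.pair_rho) * z + np.sqrt(1 - cfg.pair_rho) * rng.normal()
                log2val = (
                    baseline[gid]
                    + cfg.overlap_uplift * float(overlap_state.get((gid, lib), False))
                    + cfg.expr_sigma * eps
                )
                expr.loc[gid, lib] = float(2.0**log2val)
    for gid in singleton_ids:
        for lib in all_libs:
            if expressed.get((gid, lib), False):
                expr.loc[gid, lib] = float(
                    2.0 ** (baseline[gid] + cfg.expr_sigma * rng.normal())
                )

    # --- allele counts ----------------------------------------------------
    ase_libs = group_libs[: cfg.n_ase_libraries]
    class_names = list(cfg.ase_class_probs)
    class_p = np.array([cfg.ase_class_probs[k] for k in class_names])
    class_p = class_p / class_p.sum()
    counts: list[AlleleCount] = []

    def draw_depth() -> int:
        return int(cfg.depth_floor + rng.poisson(max(cfg.depth_mean - cfg.depth_floor, 1)))

    def snp_counts(f: float, depth: int) -> tuple[int, int]:
        minor = int(rng.binomial(depth, f))
        if rng.random() < 0.5:
            return depth - minor, minor
        return minor, depth - minor

    def plant_gene_ase(gid: str, positions: list[int], chrom: str) -> None:
        cls = class_names[int(rng.choice(len(class_names), p=class_p))]
        truth.gene_ase_class[gid] = cls
        for lib_i, lib in enumerate(ase_libs):
            lib_cls = cls
            if cls == "mixed":
                lib_cls = "monoallelic" if lib_i % 2 == 0 else "biallelic"
            truth.gene_library_ase_class[(gid, lib)] = lib_cls
            f = ASE_CLASS_FRACTIONS[lib_cls]
            for pos in positions:
                depth = draw_depth()
                ref, alt = snp_counts(f, depth)
                counts.append(AlleleCount(gid, lib, chrom, pos, ref, alt))
                truth.snp_class[(gid, lib, chrom, pos)] = lib_cls

    pair_gene_snp_positions: dict[str, list[int]] = {}
    for pair_id in pair_kind:
        geo = geometries[pair_id]
        gp_id, gm_id = pair_id.split("|")
        n_snps = int(rng.integers(cfg.n_snps_per_gene[0], cfg.n_snps_per_gene[1] + 1))
        pair_gene_snp_positions[gp_id] = [
            geo["center"] + 2000 + 50 * k for k in range(n_snps)
        ]
        n_snps = int(rng.integers(cfg.n_snps_per_gene[0], cfg.n_snps_per_gene[1] + 1))
        pair_gene_snp_positions[gm_id] = [
            geo["center"] - 2000 - 50 * k for k in range(n_snps)
        ]
        plant_gene_ase(gp_id, pair_gene_snp_positions[gp_id], "chr1")
        plant_gene_ase(gm_id, pair_gene_snp_positions[gm_id], "chr1")
    for gid in singleton_ids:
        g = gene_index[gid]
        mid = (g.span_start + g.span_end) // 2
        n_snps = int(rng.integers(cfg.n_snps_per_gene[0], cfg.n_snps_per_gene[1] + 1))
        plant_gene_ase(gid, [mid + 50 * k for k in range(n_snps)], "chr2")

    # biallelic-looking SNPs inside constitutive overlap spans: the
    # overlap-region exclusion must remove them
    const = truth.constitutive_pairs
    for k in range(cfg.n_overlap_region_snps if const else 0):
        pair_id = const[k % len(const)]
        geo = geometries[pair_id]
        gid = pair_id.split("|")[k % 2]
        pos = geo["center"] + (k % (2 * cfg.overlap_half)) - cfg.overlap_half
        depth = draw_depth()
        ref, alt = snp_counts(0.5, depth)
        counts.append(AlleleCount(gid, ase_libs[0], "chr1", pos, ref, alt))
        truth.excluded_snps[(gid, ase_libs[0], "chr1", pos)] = "overlap_region"
    # low-depth SNPs: the depth filter must remove them
    for k in range(cfg.n_low_depth_snps if singleton_ids else 0):
        gid = singleton_ids[k % len(singleton_ids)]
        g = gene_index[gid]
        pos = g.span_start + 100 + k
        ref, alt = snp_counts(0.5, 5)
        counts.append(AlleleCount(gid, ase_libs[0], "chr2", pos, ref, alt))
        truth.excluded_snps[(gid, ase_libs[0], "chr2", pos)] = "low_depth"

    # nondiploid mask over a few singleton genes
    mask = RegionMask(label="nondiploid")
    for gid in singleton_ids[: cfg.n_nondiploid_singletons]:
        g = gene_index[gid]
        mask.add(g.chrom, g.span_start - 100, g.span_end + 100)
        truth.nondiploid_genes.append(gid)

    # --- DE table, TF list, motifs, promoters ------------------------------
    tf_ids = {"TF_ACT", "TF_REP"} | {f"TF_{i:03d}" for i in range(3, 31)}
    de_rows = []
    switching_genes = [
        gid
        for pair_id, info in sorted(truth.switch_pairs.items())
        for gid, shift in info["shifts"].items()
        if shift > 0
    ]
    for gid in switching_genes:
        de_rows.append({"gene_id": gid, "log2fc": round(float(rng.uniform(2.0, 3.5)), 3), "fdr": 1e-3})
        truth.de_up.append(gid)
    de_rows.append({"gene_id": "TF_ACT", "log2fc": 3.0, "fdr": 1e-4})
    de_rows.append({"gene_id": "TF_REP", "log2fc": -3.0, "fdr": 1e-4})
    truth.de_up.append("TF_ACT")
    truth.de_down.append("TF_REP")
    for i, tf in enumerate(sorted(tf_ids - {"TF_ACT", "TF_REP"})):
        if i < 2:  # a couple more DE TFs
            lfc = 2.0 if i == 0 else -2.0
            de_rows.append({"gene_id": tf, "log2fc": lfc, "fdr": 0.01})
            (truth.de_up if lfc > 0 else truth.de_down).append(tf)
        else:
            de_rows.append(
                {"gene_id": tf, "log2fc": round(float(rng.normal(0, 0.3)), 3),
                 "fdr": round(float(rng.uniform(0.2, 1.0)), 3)}
            )
    for gid in singleton_ids:
        de_rows.append(
            {"gene_id": gid, "log2fc": round(float(rng.normal(0, 0.3)), 3),
             "fdr": round(float(rng.uniform(0.2, 1.0)), 3)}
        )
    de_table = pd.DataFrame(de_rows)

    pfms = [
        _consensus_pfm("MOTIF_ACT", "TF_ACT", ACT_CONSENSUS, cfg.motif_counts_total),
        _consensus_pfm("MOTIF_REP", "TF_REP", REP_CONSENSUS, cfg.motif_counts_total),
        _consensus_pfm("MOTIF_BG", "TF_003", BG_CONSENSUS, cfg.motif_counts_total),
    ]

    promoters: dict[str, str] = {}
    offsets: dict[str, int] = {}
    for pair_id, info in sorted(truth.switch_pairs.items()):
        geo = geometries[pair_id]
        for side, gid in zip(("plus", "minus"), pair_id.split("|")):
            if info["shifts"][gid] == 0:
                continue
            new_tss = geo[f"{side}_ov"]
            old_tss = geo[f"{side}_no"]
            win_lo = min(new_tss, old_tss) - 600
            win_hi = max(new_tss, old_tss) + 600
            seq = list("ACGT"[i] for i in rng.integers(0, 4, win_hi - win_lo))
            plants = [
                ("MOTIF_ACT", ACT_CONSENSUS, new_tss - 150, "new"),
                ("MOTIF_REP", REP_CONSENSUS, old_tss + 120, "old"),
            ]
            for motif_id, consensus, start, near in plants:
                rel = start - win_lo
                seq[rel : rel + len(consensus)] = list(consensus)
                truth.motif_plants.append(
                    {"gene_id": gid, "motif_id": motif_id, "start": start, "near": near,
                     "tss": new_tss if near == "new" else old_tss}
                )
            seq_str = _remove_spurious("".join(seq), [ACT_CONSENSUS, REP_CONSENSUS],
                                       [p[2] - win_lo for p in plants])
            promoters[gid] = seq_str
            offsets[gid] = win_lo

    return SimBundle(
        config=cfg,
        genes=genes,
        tss_records=tss_rows,
        expression=expr,
        allele_counts=counts,
        nondiploid_mask=mask,
        de_table=de_table,
        tf_ids=tf_ids,
        pfms=pfms,
        promoters=promoters,
        promoter_offsets=offsets,
        truth=truth,
    )


def _remove_spurious(seq: str, consensi: list[str], planted_starts: list[int]) -> str:
    """Mutate accidental exact consensus matches (either strand) so the
    planted instances are the only ones."""
    from .motif import reverse_complement

    chars = list(seq)
    planted = set(planted_starts)
    for consensus in consensi:
        for pattern in (consensus, reverse_complement(consensus)):
            start = 0
            while True:
                i = "".join(chars).find(pattern, start)
                if i < 0:
                    break
                if i not in planted:
                    mid = i + len(pattern) // 2
                    chars[mid] = {"A": "C", "C": "A", "G": "T", "T": "G"}[chars[mid]]
                start = i + 1
    return "".join(chars)


# ---------------------------------------------------------------------------
# writing a run directory
# ---------------------------------------------------------------------------


def write_run_dir(bundle: SimBundle, out_dir: str | Path) -> dict[str, str]:
    """Write every generated artifact in the formats the readers accept."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": out / "genes.bed",
        "tss": out / "tss.tsv",
        "expression": out / "expression.tsv",
        "allele_counts": out / "allele_counts.tsv",
        "nondiploid": out / "nondiploid.bed",
        "de": out / "de.tsv",
        "tf_list": out / "tf_list.txt",
        "pfms": out / "motifs.jaspar",
        "promoters": out / "promoters.fasta",
        "promoter_offsets": out / "promoter_offsets.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "truth": out / "truth.json",
    }
    tio.write_gene_models(bundle.genes, paths["genes"], format="BED6")
    tio.write_tss_table(bundle.tss_records, paths["tss"])
    bundle.expression.rename_axis("gene_id").to_csv(paths["expression"], sep="\t")
    tio.write_allele_counts(bundle.allele_counts, paths["allele_counts"])
    tio.write_region_mask(bundle.nondiploid_mask, paths["nondiploid"])
    tio.write_table(bundle.de_table, paths["de"])
    tio.write_gene_list(bundle.tf_ids, paths["tf_list"])
    tio.write_pfm(bundle.pfms, paths["pfms"])
    tio.write_fasta(bundle.promoters, paths["promoters"])
    pd.DataFrame(
        [{"gene_id": g, "offset": o} for g, o in sorted(bundle.promoter_offsets.items())]
    ).to_csv(paths["promoter_offsets"], sep="\t", index=False)
    # reference gene sets: pair-group memberships (enrichment stage input)
    gene_sets: dict[str, set[str]] = {}
    for pair_id, group in bundle.truth.pair_group.items():
        gene_sets.setdefault(f"pair_group_{group}", set()).update(pair_id.split("|"))
    gene_sets["singletons"] = {
        g.gene_id for g in bundle.genes if "|" not in g.gene_id and g.gene_id.startswith("SG")
    }
    tio.write_gmt(gene_sets, paths["gene_sets"])
    truth = bundle.truth
    serializable = {
        "pair_group": truth.pair_group,
        "library_group": truth.library_group,
        "pair_states": {f"{p}::{l}": s for (p, l), s in truth.pair_states.items()},
        "constitutive_pairs": truth.constitutive_pairs,
        "switch_pairs": truth.switch_pairs,
        "gene_ase_class": truth.gene_ase_class,
        "nondiploid_genes": truth.nondiploid_genes,
        "motif_plants": truth.motif_plants,
        "de_up": truth.de_up,
        "de_down": truth.de_down,
        "pair_rho": truth.pair_rho,
        "seed": bundle.config.seed,
        "control_libs": bundle.config.control_library_ids(),
        "treated_libs": bundle.config.treated_library_ids(),
    }
    paths["truth"].write_text(json.dumps(serializable, indent=1))
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------


def truth_compare(
    bundle: SimBundle,
    statuses: Sequence,
    cluster_labels: pd.Series | None = None,
    ase_calls: Sequence | None = None,
    switch_events: Sequence | None = None,
    tss_specific_hits: dict | None = None,
) -> dict:
    """Score every planted property against pipeline outputs.

    Returns a flat machine-readable dict of recovery metrics.  Inputs
    that were not computed may be passed as None and are skipped.
    """
    truth = bundle.truth
    report: dict = {}

    called = {(s.pair_id, s.library_id): s.state for s in statuses}
    keys = [k for k in truth.pair_states if k in called]
    if keys:
        agree = sum(truth.pair_states[k] == called[k] for k in keys)
        confusion: dict[str, int] = {}
        for k in keys:
            key = f"{truth.pair_states[k]}->{called[k]}"
            confusion[key] = confusion.get(key, 0) + 1
        report["overlap_call_accuracy"] = agree / len(keys)
        report["overlap_call_n"] = len(keys)
        report["overlap_call_confusion"] = confusion

    if cluster_labels is not None:
        from sklearn.metrics import adjusted_rand_score

        libs = [l for l in cluster_labels.index if l in truth.library_group]
        report["library_cluster_ari"] = float(
            adjusted_rand_score(
                [truth.library_group[l] for l in libs],
                [int(cluster_labels[l]) for l in libs],
            )
        )

    if ase_calls is not None:
        from .ase import classify_snp

        planted = truth.gene_ase_class
        scored = [
            c for c in ase_calls if c.gene_id in planted and c.excluded_reason is None
        ]
        if scored:
            report["ase_gene_accuracy"] = sum(
                c.overall == planted[c.gene_id] for c in scored
            ) / len(scored)
            report["ase_gene_n"] = len(scored)
        snp_truth = truth.snp_class
        n_ok = n_all = 0
        for c in bundle.allele_counts:
            key = (c.gene_id, c.library_id, c.chrom, c.pos)
            if key in snp_truth and c.depth >= 1:
                n_all += 1
                n_ok += classify_snp(c.ref_count, c.alt_count) == snp_truth[key]
        if n_all:
            report["ase_snp_accuracy"] = n_ok / n_all
            report["ase_snp_n"] = n_all

    if switch_events is not None:
        found = {e.pair_id for e in switch_events}
        planted_pairs = set(truth.switch_pairs)
        tp = len(found & planted_pairs)
        report["switch_precision"] = tp / len(found) if found else float("nan")
        report["switch_recall"] = tp / len(planted_pairs) if planted_pairs else float("nan")
        shift_ok = shift_n = 0
        for e in switch_events:
            info = truth.switch_pairs.get(e.pair_id)
            if info is None:
                continue
            for gid, shift in info["shifts"].items():
                if shift > 0:
                    shift_n += 1
                    shift_ok += e.upstream_shift_bp.get(gid) == shift
        if shift_n:
            report["switch_shift_accuracy"] = shift_ok / shift_n

    if tss_specific_hits is not None:
        plants = [p for p in truth.motif_plants if p["motif_id"] == "MOTIF_ACT"]
        n_ok = 0
        for p in plants:
            assoc = tss_specific_hits.get(p["gene_id"], {})
            n_ok += assoc.get("MOTIF_ACT") == p["tss"]
        if plants:
            report["motif_specific_recall"] = n_ok / len(plants)
            report["motif_specific_n"] = len(plants)

    return report
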