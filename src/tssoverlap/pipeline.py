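"""End-to-end orchestration over a run directory of plain files.

Every stage reads and writes tab-separated files in one directory, so
stages are independently runnable, resumable and diffable.  A manifest
records the tool version, per-stage parameters, row counts, wall time
and SHA-256 digests of inputs and outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd

from . import __version__
from . import ase as ase_mod
from . import io as tio
from . import matrix as matrix_mod
from . import overlap as overlap_mod
from . import switches as switches_mod
from .expression import (
    correlate_contrast_pairs,
    expression_by_category,
    expression_by_tss_count,
    paired_overlap_test,
    select_contrast_pairs,
)
from .motif import pfm_to_pwm, scan_many
from .tss_filter import FilterConfig, filter_tss, tss_count_per_gene_library, tss_usage_stats

STAGES = ("filter", "call-overlap", "cluster", "expression-stats", "ase", "scan", "switches", "enrich")


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineError(RuntimeError):
    pass


def _require(run_dir: Path, name: str, produced_by: str) -> Path:
    p = run_dir / name
    if not p.exists():
        raise PipelineError(f"missing {name}; run the '{produced_by}' stage first")
    return p


def run_all(
    run_dir: str | Path,
    filter_config: FilterConfig | None = None,
    n_clusters: int = 3,
    min_each: int = 10,
    skip: set[str] | frozenset = frozenset(),
) -> dict:
    """Execute every stage in dependency order; returns the manifest.

    Stage names in ``skip`` are marked skipped; downstream stages that
    can still run, do.  Outputs are a pure function of the inputs, so
    re-running with identical inputs reproduces identical files.
    """
    run_dir = Path(run_dir)
    cfg = filter_config or FilterConfig()
    manifest: dict = {
        "tool": "tssoverlap",
        "version": __version__,
        "run_dir": str(run_dir),
        "parameters": {
            "min_ppm": cfg.min_ppm,
            "max_distance_bp": cfg.max_distance_bp,
            "require_confident": cfg.require_confident,
            "n_clusters": n_clusters,
            "min_each": min_each,
        },
        "inputs": {},
        "stages": [],
    }
    for name in ("genes.bed", "tss.tsv", "expression.tsv"):
        p = run_dir / name
        if p.exists():
            manifest["inputs"][name] = _digest(p)

    genes = tio.read_gene_models(_require(run_dir, "genes.bed", "simulate"), format="BED6")
    gene_map = {g.gene_id: g for g in genes}

    def stage(name: str, fn) -> dict | None:
        entry: dict = {"stage": name}
        if name in skip:
            entry["status"] = "skipped"
            manifest["stages"].append(entry)
            return None
        t0 = time.perf_counter()
        try:
            result = fn(entry)
        except PipelineError as exc:
            entry["status"] = "error"
            entry["error"] = str(exc)
            manifest["stages"].append(entry)
            raise
        entry["status"] = "ok"
        entry["wall_time_s"] = round(time.perf_counter() - t0, 3)
        entry["outputs"] = {
            n: _digest(run_dir / n) for n in entry.get("output_files", [])
        }
        entry.pop("output_files", None)
        manifest["stages"].append(entry)
        return result

    # ---- filter ----------------------------------------------------------
    def do_filter(entry):
        records, _ = tio.read_tss_table(_require(run_dir, "tss.tsv", "simulate"), genes)
        admitted, report = filter_tss(records, genes, cfg)
        tio.write_tss_table(admitted, run_dir / "admitted_tss.tsv")
        tio.write_table(report.to_frame(), run_dir / "rejection_report.tsv")
        tio.write_table(
            tss_usage_stats(admitted).reset_index(), run_dir / "tss_usage_stats.tsv"
        )
        entry["n_input"] = report.n_input
        entry["n_admitted"] = report.n_admitted
        entry["output_files"] = ["admitted_tss.tsv", "rejection_report.tsv", "tss_usage_stats.tsv"]
        return admitted

    admitted = stage("filter", do_filter)

    # ---- call-overlap ----------------------------------------------------
    def do_call(entry):
        recs = admitted
        if recs is None:
            recs, _ = tio.read_tss_table(_require(run_dir, "admitted_tss.tsv", "filter"), genes)
        pairs = overlap_mod.candidate_pairs(genes)
        libraries = sorted({r.library_id for r in recs})
        statuses = overlap_mod.call_all(pairs, gene_map, recs, libraries)
        tio.write_table(overlap_mod.statuses_to_frame(statuses), run_dir / "statuses.tsv")
        summary = overlap_mod.pair_library_summary(statuses)
        tio.write_table(summary.per_pair.reset_index(), run_dir / "pair_summary.tsv")
        tio.write_gene_list(summary.always_overlap, run_dir / "always_overlap_pairs.txt")
        entry["n_pairs"] = len(pairs)
        entry["n_libraries"] = len(libraries)
        entry["n_always_overlap"] = len(summary.always_overlap)
        entry["output_files"] = ["statuses.tsv", "pair_summary.tsv", "always_overlap_pairs.txt"]
        return statuses, recs

    called = stage("call-overlap", do_call)
    statuses, admitted = called if called else (None, admitted)

    # ---- cluster ---------------------------------------------------------
    def do_cluster(entry):
        sts = statuses
        if sts is None:
            sts = overlap_mod.statuses_from_frame(
                tio.read_table(_require(run_dir, "statuses.tsv", "call-overlap"))
            )
        mat = matrix_mod.build_overlap_matrix(sts)
        mat.rename_axis("pair_id").to_csv(run_dir / "overlap_matrix.tsv", sep="\t")
        if mat.empty:
            entry["n_matrix_rows"] = 0
            entry["output_files"] = ["overlap_matrix.tsv"]
            return None
        clust = matrix_mod.cluster_bidirectional(mat, n_clusters, n_clusters)
        clust.col_labels.rename("cluster").rename_axis("library_id").reset_index().to_csv(
            run_dir / "clusters_libraries.tsv", sep="\t", index=False
        )
        clust.row_labels.rename("cluster").rename_axis("pair_id").reset_index().to_csv(
            run_dir / "clusters_pairs.tsv", sep="\t", index=False
        )
        entry["n_matrix_rows"] = mat.shape[0]
        entry["n_matrix_cols"] = mat.shape[1]
        entry["output_files"] = ["overlap_matrix.tsv", "clusters_libraries.tsv", "clusters_pairs.tsv"]
        return clust

    cluster_result = stage("cluster", do_cluster)

    # ---- expression-stats ------------------------------------------------
    def do_expression(entry):
        sts = statuses
        if sts is None:
            sts = overlap_mod.statuses_from_frame(
                tio.read_table(_require(run_dir, "statuses.tsv", "call-overlap"))
            )
        expr = tio.read_table(_require(run_dir, "expression.tsv", "simulate"), key="gene_id")
        contrast = select_contrast_pairs(sts, min_each=min_each)
        entry["n_contrast_pairs"] = len(contrast)
        results: dict = {}
        if contrast:
            verdicts = correlate_contrast_pairs(contrast, expr)
            tio.write_table(verdicts, run_dir / "correlation_verdicts.tsv")
            paired = paired_overlap_test(contrast, expr)
            results["paired_t"] = {
                "t": paired.t,
                "p": paired.p,
                "n_genes": paired.n_genes,
                "mean_overlap": paired.mean_overlap,
                "mean_no_overlap": paired.mean_no_overlap,
            }
        counts = tss_count_per_gene_library(admitted) if admitted else pd.Series(dtype=int)
        obs, mwu = expression_by_tss_count(dict(counts.items()), expr)
        tio.write_table(mwu, run_dir / "tss_count_tests.tsv")
        cats = overlap_mod.gene_category_frame(sts, dict(counts.items()))
        _, cat_tests = expression_by_category(cats, expr)
        tio.write_table(cat_tests, run_dir / "category_tests.tsv")
        (run_dir / "expression_tests.json").write_text(json.dumps(results, indent=1))
        entry["output_files"] = [
            "tss_count_tests.tsv",
            "category_tests.tsv",
            "expression_tests.json",
        ] + (["correlation_verdicts.tsv"] if contrast else [])
        return results

    stage("expression-stats", do_expression)

    # ---- ase -------------------------------------------------------------
    def do_ase(entry):
        sts = statuses
        if sts is None:
            sts = overlap_mod.statuses_from_frame(
                tio.read_table(_require(run_dir, "statuses.tsv", "call-overlap"))
            )
        counts_path = run_dir / "allele_counts.tsv"
        if not counts_path.exists():
            raise PipelineError("missing allele_counts.tsv; run the 'simulate' stage first")
        counts = tio.read_allele_counts(counts_path)
        expr = tio.read_table(_require(run_dir, "expression.tsv", "simulate"), key="gene_id")
        nondiploid = None
        if (run_dir / "nondiploid.bed").exists():
            nondiploid = tio.read_region_mask(run_dir / "nondiploid.bed", label="nondiploid")
        exclusion = ase_mod.exclude_genes(genes, nondiploid, expr)
        overlap_mask = ase_mod.overlap_regions_mask(sts, gene_map)
        calls = ase_mod.classify_genes(counts, exclusion.analyzable, overlap_mask)
        tio.write_table(ase_mod.calls_to_frame(calls), run_dir / "ase_calls.tsv")
        pair_genes = {g for s in sts for g in s.pair_id.split("|")}
        overlap_calls = [c for c in calls if c.gene_id in pair_genes]
        control_calls = [c for c in calls if c.gene_id not in pair_genes]
        if overlap_calls and control_calls:
            summary = ase_mod.mae_summary(overlap_calls, control_calls)
            tio.write_table(summary.to_frame(), run_dir / "mae_summary.tsv")
        entry["n_analyzable"] = len(exclusion.analyzable)
        entry["n_excluded"] = len(exclusion.excluded)
        entry["output_files"] = ["ase_calls.tsv"] + (
            ["mae_summary.tsv"] if overlap_calls and control_calls else []
        )
        return calls

    stage("ase", do_ase)

    # ---- scan ------------------------------------------------------------
    def do_scan(entry):
        fasta = run_dir / "promoters.fasta"
        pfm_path = run_dir / "motifs.jaspar"
        if not fasta.exists() or not pfm_path.exists():
            raise PipelineError("missing promoters.fasta/motifs.jaspar; run the 'simulate' stage first")
        seqs = tio.read_fasta(fasta)
        pfms = tio.read_pfm(pfm_path)
        offsets = {}
        if (run_dir / "promoter_offsets.tsv").exists():
            off = tio.read_table(run_dir / "promoter_offsets.tsv")
            offsets = dict(zip(off["gene_id"], off["offset"].astype(int)))
        pwms = [pfm_to_pwm(p) for p in pfms]
        hits = scan_many(seqs, pwms, offsets=offsets)
        lengths = {p.motif_id: p.length for p in pfms}
        df = pd.DataFrame(
            [
                {
                    "sequence": h.chrom,
                    "start": h.start,
                    "end": h.start + lengths[h.motif_id],
                    "motif_id": h.motif_id,
                    "strand": h.strand,
                    "rel_score": h.rel_score,
                    "raw_score": h.raw_score,
                }
                for h in hits
            ]
        )
        tio.write_table(df, run_dir / "motif_hits.tsv")
        entry["n_hits"] = len(df)
        entry["output_files"] = ["motif_hits.tsv"]
        return hits, lengths

    scanned = stage("scan", do_scan)

    # ---- switches --------------------------------------------------------
    def do_switches(entry):
        sts = statuses
        if sts is None:
            sts = overlap_mod.statuses_from_frame(
                tio.read_table(_require(run_dir, "statuses.tsv", "call-overlap"))
            )
        truth_path = run_dir / "truth.json"
        if not truth_path.exists():
            raise PipelineError("missing truth.json naming control/treated libraries")
        meta = json.loads(truth_path.read_text())
        control, treated = meta["control_libs"], meta["treated_libs"]
        recs = admitted
        if recs is None:
            recs, _ = tio.read_tss_table(_require(run_dir, "admitted_tss.tsv", "filter"), genes)
        events = switches_mod.detect_switches(sts, gene_map, recs, control, treated)
        tio.write_table(switches_mod.events_to_frame(events), run_dir / "switch_events.tsv")
        de = tio.read_table(_require(run_dir, "de.tsv", "simulate"))
        up, down = switches_mod.apply_de_thresholds(de)
        tfs = tio.read_gene_list(_require(run_dir, "tf_list.txt", "simulate"))
        up_tf, down_tf = switches_mod.intersect_tf(up, down, tfs)
        tio.write_table(
            pd.DataFrame(
                [{"tf": t, "direction": "up"} for t in sorted(up_tf)]
                + [{"tf": t, "direction": "down"} for t in sorted(down_tf)]
            ),
            run_dir / "de_tfs.tsv",
        )
        assoc_rows = []
        if scanned:
            hits, lengths = scanned
            by_gene_hits: dict[str, list] = {}
            for h in hits:
                by_gene_hits.setdefault(h.chrom, []).append(h)
            for event in events:
                for gid in event.switching_genes:
                    tss = sorted(
                        {
                            r.position
                            for r in recs
                            if r.gene_id == gid and r.library_id in set(control) | set(treated)
                        }
                    )
                    assoc = switches_mod.associate_tss_tfbs(
                        gid, tss, by_gene_hits.get(gid, []), lengths
                    )
                    for motif_id, pos in sorted(assoc.tss_specific.items()):
                        assoc_rows.append(
                            {"gene_id": gid, "motif_id": motif_id, "tss": pos, "tss_specific": True}
                        )
        tio.write_table(
            pd.DataFrame(assoc_rows, columns=["gene_id", "motif_id", "tss", "tss_specific"]),
            run_dir / "tss_tf_associations.tsv",
        )
        entry["n_events"] = len(events)
        entry["n_de_tfs_up"] = len(up_tf)
        entry["n_de_tfs_down"] = len(down_tf)
        entry["output_files"] = ["switch_events.tsv", "de_tfs.tsv", "tss_tf_associations.tsv"]
        return events

    stage("switches", do_switches)

    # ---- enrich ----------------------------------------------------------
    def do_enrich(entry):
        gmt = run_dir / "gene_sets.gmt"
        if not gmt.exists():
            entry["note"] = "no gene_sets.gmt present"
            entry["output_files"] = []
            return None
        sts = statuses
        if sts is None:
            sts = overlap_mod.statuses_from_frame(
                tio.read_table(_require(run_dir, "statuses.tsv", "call-overlap"))
            )
        reference = tio.read_gmt(gmt)
        universe = {g.gene_id for g in genes}
        meta_path = run_dir / "truth.json"
        lib_group = {}
        if meta_path.exists():
            lib_group = json.loads(meta_path.read_text()).get("library_group", {})
        frames = []
        groups = sorted(set(lib_group.values())) or ["all"]
        for grp in groups:
            libs = {l for l, g in lib_group.items() if g == grp} if lib_group else None
            query = {
                g
                for s in sts
                if s.state == "overlap" and (libs is None or s.library_id in libs)
                for g in s.pair_id.split("|")
            }
            if not query:
                continue
            res = matrix_mod.enrich(query, reference, universe)
            df = matrix_mod.enrichment_frame(res)
            df.insert(0, "group", grp)
            frames.append(df)
        out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        tio.write_table(out, run_dir / "enrichment.tsv")
        entry["n_rows"] = len(out)
        entry["output_files"] = ["enrichment.tsv"]
        return out

    stage("enrich", do_enrich)

    # ---- recovery vs planted truth ---------------------------------------
    recovery = compute_recovery(run_dir)
    if recovery is not None:
        (run_dir / "recovery.json").write_text(json.dumps(recovery, indent=1))
        manifest["recovery"] = recovery

    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def compute_recovery(run_dir: str | Path) -> dict | None:
    """Score stage outputs against truth.json, if present."""
    run_dir = Path(run_dir)
    truth_path = run_dir / "truth.json"
    if not truth_path.exists():
        return None
    meta = json.loads(truth_path.read_text())
    report: dict = {}

    if (run_dir / "statuses.tsv").exists():
        sts = tio.read_table(run_dir / "statuses.tsv")
        called = {
            (r.pair_id, r.library_id): r.state for r in sts.itertuples(index=False)
        }
        truth_states = {
            tuple(k.split("::")): v for k, v in meta["pair_states"].items()
        }
        keys = [k for k in truth_states if k in called]
        if keys:
            report["overlap_call_accuracy"] = sum(
                truth_states[k] == called[k] for k in keys
            ) / len(keys)
            report["overlap_call_n"] = len(keys)

    if (run_dir / "always_overlap_pairs.txt").exists():
        always = tio.read_gene_list(run_dir / "always_overlap_pairs.txt")
        planted = set(meta["constitutive_pairs"])
        report["constitutive_recall"] = (
            len(always & planted) / len(planted) if planted else float("nan")
        )

    if (run_dir / "overlap_matrix.tsv").exists():
        from sklearn.metrics import adjusted_rand_score

        # library-group recovery is judged on the grouped libraries only;
        # dedicated condition (control/treated) libraries are not part of
        # the planted three-group structure
        lib_group = meta["library_group"]
        mat = tio.read_table(run_dir / "overlap_matrix.tsv", key="pair_id")
        cols = [c for c in mat.columns if c in lib_group]
        k = len(set(lib_group.values()))
        if len(cols) > k:
            clust = matrix_mod.cluster_bidirectional(mat[cols], k, k)
            report["library_cluster_ari"] = float(
                adjusted_rand_score(
                    [lib_group[l] for l in cols],
                    [int(clust.col_labels[l]) for l in cols],
                )
            )

    if (run_dir / "ase_calls.tsv").exists():
        calls = tio.read_table(run_dir / "ase_calls.tsv").fillna("")
        planted = meta["gene_ase_class"]
        scored = calls[
            calls["gene_id"].isin(planted) & (calls["excluded_reason"] == "")
        ]
        if len(scored):
            report["ase_gene_accuracy"] = float(
                (scored["overall"] == scored["gene_id"].map(planted)).mean()
            )
            report["ase_gene_n"] = int(len(scored))

    if (run_dir / "switch_events.tsv").exists():
        events = tio.read_table(run_dir / "switch_events.tsv")
        found = set(events["pair_id"]) if len(events) else set()
        planted = set(meta["switch_pairs"])
        tp = len(found & planted)
        report["switch_precision"] = tp / len(found) if found else float("nan")
        report["switch_recall"] = tp / len(planted) if planted else float("nan")

    if (run_dir / "tss_tf_associations.tsv").exists():
        assoc = tio.read_table(run_dir / "tss_tf_associations.tsv")
        plants = [p for p in meta["motif_plants"] if p["motif_id"] == "MOTIF_ACT"]
        n_ok = 0
        for p in plants:
            rows = assoc[
                (assoc["gene_id"] == p["gene_id"]) & (assoc["motif_id"] == "MOTIF_ACT")
            ]
            n_ok += bool(len(rows)) and int(rows.iloc[0]["tss"]) == p["tss"]
        if plants:
            report["motif_specific_recall"] = n_ok / len(plants)

    return report
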