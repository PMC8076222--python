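"""Overlap calling: effective 5' ends, candidate search, verdict oracle,
summaries and the six-way categorisation."""

import numpy as np
import pytest

from oracles import make_records, overlap_oracle, random_pair_config
from tssoverlap.models import GeneModel, GenePair
from tssoverlap.overlap import (
    call_all,
    call_overlap,
    candidate_pairs,
    effective_five_prime,
    gene_category_frame,
    pair_library_summary,
    six_category,
)


def _gene(gene_id, strand, start, end):
    return GeneModel(gene_id, "chr1", strand, start, end)


class TestEffectiveFivePrime:
    def test_plus_strand_takes_minimum(self):
        g = _gene("G", "+", 0, 1000)
        assert effective_five_prime(g, make_records(g, "L", [100, 150])) == 100

    def test_minus_strand_takes_maximum(self):
        g = _gene("G", "-", 0, 1000)
        assert effective_five_prime(g, make_records(g, "L", [100, 150])) == 150

    def test_no_tss_is_absent(self):
        assert effective_five_prime(_gene("G", "+", 0, 1000), []) is None


class TestCandidatePairs:
    def test_opposite_strand_heads_1kb_apart_found(self):
        gp = _gene("A", "+", 5_000, 9_000)
        gm = _gene("B", "-", 1_000, 6_001)  # minus 5' at 6_000, 1 kb from plus 5'
        pairs = candidate_pairs([gp, gm], max_gap_bp=11_000)
        assert len(pairs) == 1 and pairs[0].pair_id == "A|B"

    def test_same_strand_genes_never_pair(self):
        pairs = candidate_pairs([_gene("A", "+", 0, 1000), _gene("B", "+", 100, 900)])
        assert pairs == []

    def test_completeness_against_exhaustive_overlap_scan(self):
        """Any pair the brute-force scan can ever call overlapping (over
        random admitted-TSS choices within the 5 kb radius) is in the
        candidate set."""
        rng = np.random.default_rng(5)
        for _ in range(200):
            pair, gp, gm, tp, tm = random_pair_config(rng)
            verdict, _ = overlap_oracle(gp, gm, tp, tm)
            if verdict != "overlap":
                continue
            found = candidate_pairs([gp, gm], max_gap_bp=10_000)
            assert [p.pair_id for p in found] == ["GP|GM"]


class TestCallOverlap:
    GENES = {
        "GP": _gene("GP", "+", 50, 1000),
        "GM": _gene("GM", "-", 0, 500),
    }
    PAIR = GenePair("GP|GM", "GP", "GM", "chr1")

    def call(self, pos_plus, pos_minus):
        return call_overlap(
            self.PAIR,
            "L1",
            self.GENES,
            make_records(self.GENES["GP"], "L1", pos_plus),
            make_records(self.GENES["GM"], "L1", pos_minus),
        )

    def test_single_shared_base_is_an_overlap(self):
        s = self.call([100], [100])
        assert s.state == "overlap" and s.overlap_len_bp == 1

    def test_one_base_miss_is_no_overlap(self):
        s = self.call([100], [99])
        assert s.state == "no_overlap" and s.overlap_len_bp == 0

    def test_expression_states(self):
        assert self.call([], []).state == "none_expressed"
        assert self.call([100], []).state == "single_expressed"

    def test_tss_classes_and_fraction(self):
        s = self.call([100, 300], [200])
        assert s.state == "overlap" and s.overlap_len_bp == 101
        assert (s.tss_class_plus, s.tss_class_minus) == ("multiple", "single")
        # one of the plus gene's two equally expressed TSSs is inside [100, 200]
        assert s.fraction_overlapping_plus == pytest.approx(0.5)
        assert s.fraction_overlapping_minus == pytest.approx(1.0)

    def test_different_chromosome_pair_is_an_error(self):
        genes = dict(self.GENES)
        genes["GM"] = GeneModel("GM", "chr2", "-", 0, 500)
        with pytest.raises(ValueError):
            call_overlap(self.PAIR, "L1", genes, [], [])

    def test_randomized_verdicts_match_base_set_oracle(self):
        rng = np.random.default_rng(17)
        n_overlap = 0
        for _ in range(1000):
            pair, gp, gm, tp, tm = random_pair_config(rng)
            status = call_overlap(
                pair, "L", {"GP": gp, "GM": gm},
                make_records(gp, "L", tp), make_records(gm, "L", tm),
            )
            verdict, length = overlap_oracle(gp, gm, tp, tm)
            assert status.state == verdict
            assert status.overlap_len_bp == length
            n_overlap += verdict == "overlap"
        assert n_overlap > 50  # the geometry generator exercises real overlaps

    def test_upstream_move_preserves_overlap(self):
        """Monotonicity of the shared-base predicate: moving one gene's
        effective 5' end further upstream never destroys an existing
        overlap while the partner is unchanged.  (The optional
        head-to-head geometry rule is a separate, non-monotone filter:
        a 5' end can leave the partner's extent.)"""
        rng = np.random.default_rng(23)
        checked = 0
        while checked < 200:
            pair, gp, gm, tp, tm = random_pair_config(rng)
            if not tp or not tm:
                continue
            base = call_overlap(pair, "L", {"GP": gp, "GM": gm},
                                make_records(gp, "L", tp), make_records(gm, "L", tm),
                                require_head_to_head=False)
            if base.state != "overlap":
                continue
            moved = call_overlap(
                pair, "L", {"GP": gp, "GM": gm},
                make_records(gp, "L", tp + [min(tp) - int(rng.integers(1, 500))]),
                make_records(gm, "L", tm),
                require_head_to_head=False,
            )
            assert moved.state == "overlap"
            assert moved.overlap_len_bp >= base.overlap_len_bp
            checked += 1


class TestSummaries:
    def test_pair_summary_counts_and_always_overlap(self, small_bundle):
        from tssoverlap.overlap import call_all
        from tssoverlap.tss_filter import filter_tss

        b = small_bundle
        admitted, _ = filter_tss(b.tss_records, b.genes)
        pairs = candidate_pairs(b.genes)
        statuses = call_all(pairs, b.genes, admitted, b.all_library_ids)
        summary = pair_library_summary(statuses)
        pp = summary.per_pair
        assert (pp["n_libraries_overlap"] <= pp["n_libraries_both_expressed"]).all()
        assert set(summary.always_overlap) >= set(b.truth.constitutive_pairs)

    def test_manual_counting(self):
        from tssoverlap.models import PairLibraryStatus

        statuses = [
            PairLibraryStatus("P", f"L{i}", "overlap" if i < 3 else "no_overlap")
            for i in range(10)
        ]
        summary = pair_library_summary(statuses)
        assert summary.per_pair.loc["P", "n_libraries_both_expressed"] == 10
        assert summary.per_pair.loc["P", "n_libraries_overlap"] == 3
        assert summary.always_overlap == []


class TestSixCategories:
    def test_truth_table_reaches_all_six_unambiguously(self):
        seen = set()
        for state in ("overlap", "no_overlap", "single_expressed"):
            for n in (1, 2, 3):
                cat = six_category(state, n)
                assert cat is not None
                seen.add(cat)
        assert len(seen) == 6

    def test_none_expressed_takes_no_category(self):
        assert six_category("none_expressed", 0) is None
        assert six_category("overlap", 0) is None

    def test_category_frame_partitions_observations(self, small_bundle):
        from tssoverlap.tss_filter import filter_tss, tss_count_per_gene_library

        b = small_bundle
        admitted, _ = filter_tss(b.tss_records, b.genes)
        pairs = candidate_pairs(b.genes)
        statuses = call_all(pairs, b.genes, admitted, b.all_library_ids)
        counts = dict(tss_count_per_gene_library(admitted).items())
        frame = gene_category_frame(statuses, counts)
        n_expressed = sum(
            (s.tss_class_plus != "absent") + (s.tss_class_minus != "absent")
            for s in statuses
            if s.state != "none_expressed"
        )
        assert len(frame) == n_expressed
        assert set(frame["category"]) <= {
            f"{a}_{b}" for a in ("overlap", "no_overlap", "single_expressed")
            for b in ("single", "multi")
        }
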