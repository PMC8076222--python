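"""Promoter-switch detection, DE thresholds, TF/motif association."""

import numpy as np
import pandas as pd
import pytest

from tssoverlap.models import GeneModel, PairLibraryStatus, TssRecord
from tssoverlap.motif import MotifHit
from tssoverlap.switches import (
    apply_de_thresholds,
    associate_tss_tfbs,
    detect_switches,
    intersect_tf,
)

GENES = {
    "GP": GeneModel("GP", "chr1", "+", 900, 9000),
    "GM": GeneModel("GM", "chr1", "-", 0, 1100),
}
CTRL = ["c1", "c2"]
TRT = ["t1", "t2", "t3", "t4"]


def tss(gene, lib, pos):
    g = GENES[gene]
    return TssRecord(gene, lib, "chr1", g.strand, pos, 10.0)


def make_case(treated_overlapping=4, additional=True):
    """Planted switch: plus gene moves from TSS 2000 to 950 on treatment."""
    statuses, records = [], []
    for lib in CTRL:
        statuses.append(PairLibraryStatus("GP|GM", lib, "no_overlap"))
        records += [tss("GP", lib, 2000), tss("GM", lib, 1050)]
    for i, lib in enumerate(TRT):
        overlapping = i < treated_overlapping
        statuses.append(
            PairLibraryStatus("GP|GM", lib, "overlap" if overlapping else "no_overlap")
        )
        if overlapping:
            records.append(tss("GP", lib, 950))
            if additional:
                records.append(tss("GP", lib, 2000))
        else:
            records.append(tss("GP", lib, 2000))
        records.append(tss("GM", lib, 1050))
    return statuses, records


class TestDetectSwitches:
    def test_full_switch_detected_with_shift_and_additional_flag(self):
        statuses, records = make_case()
        (event,) = detect_switches(statuses, GENES, records, CTRL, TRT)
        assert event.pair_id == "GP|GM"
        assert event.switching_genes == ["GP"]
        assert event.upstream_shift_bp["GP"] == 1050  # 2000 -> 950, plus strand
        assert event.new_tss_is_additional["GP"] is True

    def test_new_tss_replacing_old_is_not_additional(self):
        statuses, records = make_case(additional=False)
        (event,) = detect_switches(statuses, GENES, records, CTRL, TRT)
        assert event.new_tss_is_additional["GP"] is False

    def test_three_of_four_treated_is_not_reported(self):
        statuses, records = make_case(treated_overlapping=3)
        assert detect_switches(statuses, GENES, records, CTRL, TRT) == []

    def test_minus_strand_upstream_shift_is_positive(self):
        statuses, records = [], []
        for lib in CTRL:
            statuses.append(PairLibraryStatus("GP|GM", lib, "no_overlap"))
            records += [tss("GP", lib, 950), tss("GM", lib, 920)]
        for lib in TRT:
            statuses.append(PairLibraryStatus("GP|GM", lib, "overlap"))
            records += [tss("GP", lib, 950), tss("GM", lib, 1050)]
        (event,) = detect_switches(statuses, GENES, records, CTRL, TRT)
        assert event.switching_genes == ["GM"]
        assert event.upstream_shift_bp["GM"] == 130  # 920 -> 1050 on minus strand

    def test_overlapping_library_sets_rejected(self):
        with pytest.raises(ValueError):
            detect_switches([], GENES, [], ["a"], ["a", "b"])

    def test_antitone_in_treated_set(self):
        """Adding a treated library can only shrink the event set."""
        statuses, records = make_case(treated_overlapping=4)
        extra = "t5"
        statuses.append(PairLibraryStatus("GP|GM", extra, "no_overlap"))
        records += [tss("GP", extra, 2000), tss("GM", extra, 1050)]
        with_extra = detect_switches(statuses, GENES, records, CTRL, TRT + [extra])
        base = detect_switches(statuses, GENES, records, CTRL, TRT)
        assert {e.pair_id for e in with_extra} <= {e.pair_id for e in base}

    def test_planted_scenario_recovered_exactly(self, small_bundle):
        from tssoverlap.overlap import call_all, candidate_pairs
        from tssoverlap.tss_filter import filter_tss

        b = small_bundle
        admitted, _ = filter_tss(b.tss_records, b.genes)
        statuses = call_all(candidate_pairs(b.genes), b.genes, admitted, b.all_library_ids)
        events = detect_switches(
            statuses, {g.gene_id: g for g in b.genes}, admitted,
            b.config.control_library_ids(), b.config.treated_library_ids(),
        )
        assert {e.pair_id for e in events} == set(b.truth.switch_pairs)
        for e in events:
            info = b.truth.switch_pairs[e.pair_id]
            expected_movers = {g for g, s in info["shifts"].items() if s > 0}
            assert set(e.switching_genes) == expected_movers
            for g in expected_movers:
                assert e.upstream_shift_bp[g] == info["shifts"][g] > 0


class TestDeThresholds:
    TABLE = pd.DataFrame(
        {
            "gene_id": ["a", "b", "c", "d", "e"],
            "log2fc": [1.5, 2.0, 2.0, -2.0, -1.2],
            "fdr": [0.01, 0.05, 0.01, 0.001, 0.001],
        }
    )

    def test_strict_boundaries(self):
        up, down = apply_de_thresholds(self.TABLE)
        assert up == {"c"}  # a: lfc not > 1.5; b: fdr not < 0.05
        assert down == {"d"}

    def test_random_table_matches_predicate_scan(self):
        rng = np.random.default_rng(21)
        table = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(500)],
                "log2fc": rng.normal(0, 2, 500),
                "fdr": rng.uniform(0, 1, 500),
            }
        )
        up, down = apply_de_thresholds(table)
        for r in table.itertuples(index=False):
            assert (r.gene_id in up) == (r.log2fc > 1.5 and r.fdr < 0.05)
            assert (r.gene_id in down) == (r.log2fc < -1.5 and r.fdr < 0.05)

    def test_tf_intersection(self):
        up, down = {"a", "b"}, {"c"}
        assert intersect_tf(up, down, {"x"}) == (set(), set())
        assert intersect_tf(up, down, {"a", "b", "c"}) == ({"a", "b"}, {"c"})
        rng = np.random.default_rng(1)
        de = {f"g{i}" for i in rng.integers(0, 100, 30)}
        tfs = {f"g{i}" for i in rng.integers(0, 100, 30)}
        got_up, _ = intersect_tf(de, set(), tfs)
        assert got_up == de & tfs


class TestTssTfAssociation:
    def hit(self, motif_id, midpoint, L=1):
        # length-1 motif: start == midpoint
        return MotifHit(motif_id, "G", midpoint, "+", 1.0, 1.0)

    def test_window_boundary_inclusive_at_500(self):
        assoc = associate_tss_tfbs("G", [10_000], [self.hit("M", 10_500)], {"M": 1})
        assert assoc.per_tss[10_000] == {"M"}
        assoc = associate_tss_tfbs("G", [10_000], [self.hit("M", 10_501)], {"M": 1})
        assert assoc.per_tss[10_000] == set()

    def test_tss_specificity(self):
        tss = [10_000, 12_000]
        near_both = self.hit("MB", 11_000)  # 1000 bp from either... too far
        near_first = self.hit("M1", 10_100)
        shared = self.hit("MS", 10_000)
        hits = [near_first, shared, near_both]
        assoc = associate_tss_tfbs("G", tss, hits, {"M1": 1, "MS": 1, "MB": 1})
        assert assoc.tss_specific["M1"] == 10_000
        assert assoc.tss_specific["MS"] == 10_000
        assert "MB" not in assoc.tss_specific  # associated with neither TSS

    def test_motif_near_both_tss_not_specific(self):
        tss = [10_000, 10_600]
        both = self.hit("M", 10_300)  # 300 bp from each
        assoc = associate_tss_tfbs("G", tss, [both], {"M": 1})
        assert assoc.per_tss[10_000] == {"M"} and assoc.per_tss[10_600] == {"M"}
        assert assoc.tss_specific == {}

    def test_midpoint_anchor_uses_motif_length(self):
        # start 10_495, length 11 -> midpoint 10_500: inside the window
        hit = MotifHit("M", "G", 10_495, "+", 1.0, 1.0)
        assoc = associate_tss_tfbs("G", [10_000], [hit], {"M": 11})
        assert assoc.per_tss[10_000] == {"M"}
        # same start with length 13 -> midpoint 10_501: outside
        assoc = associate_tss_tfbs("G", [10_000], [MotifHit("M", "G", 10_495, "+", 1, 1)], {"M": 13})
        assert assoc.per_tss[10_000] == set()
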