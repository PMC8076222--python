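"""Contrast selection, correlation classes, paired t-test, group tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import mann_whitney_u_oracle, pearson_oracle
from tssoverlap.expression import (
    ContrastPair,
    correlate_pair,
    expression_by_category,
    expression_by_tss_count,
    paired_overlap_test,
    select_contrast_pairs,
)
from tssoverlap.models import PairLibraryStatus


def make_statuses(pair, n_overlap, n_no_overlap, n_single=0):
    out = []
    i = 0
    for _ in range(n_overlap):
        out.append(PairLibraryStatus(pair, f"L{i}", "overlap")); i += 1
    for _ in range(n_no_overlap):
        out.append(PairLibraryStatus(pair, f"L{i}", "no_overlap")); i += 1
    for _ in range(n_single):
        out.append(PairLibraryStatus(pair, f"L{i}", "single_expressed")); i += 1
    return out


class TestSelection:
    def test_boundary_inclusion_at_ten_and_ten(self):
        statuses = make_statuses("A|B", 10, 10)
        (cp,) = select_contrast_pairs(statuses)
        assert len(cp.libs_overlap) == 10 and len(cp.libs_no_overlap) == 10

    def test_nine_overlap_libraries_excluded(self):
        assert select_contrast_pairs(make_statuses("A|B", 9, 50)) == []

    def test_single_expressed_libraries_do_not_count(self):
        assert select_contrast_pairs(make_statuses("A|B", 10, 9, n_single=5)) == []

    def test_selection_equals_brute_force_recount(self):
        rng = np.random.default_rng(3)
        statuses, expected = [], set()
        for p in range(30):
            n_ov, n_no = int(rng.integers(0, 20)), int(rng.integers(0, 20))
            statuses += make_statuses(f"A{p}|B{p}", n_ov, n_no)
            if n_ov >= 10 and n_no >= 10:
                expected.add(f"A{p}|B{p}")
        assert {c.pair_id for c in select_contrast_pairs(statuses)} == expected


class TestCorrelation:
    def expr(self, a, b, libs):
        return pd.DataFrame([a, b], index=["GA", "GB"], columns=libs)

    def test_perfect_linearity_positive(self):
        libs = [f"L{i}" for i in range(10)]
        x = np.arange(10, dtype=float) + 1
        v = correlate_pair("GA|GB", "GA", "GB", self.expr(x, 2 * x + 1, libs), libs,
                           "overlap", log_transform=False)
        assert v.r == pytest.approx(1.0) and v.klass == "positive"

    def test_perfect_anticorrelation_negative(self):
        libs = [f"L{i}" for i in range(10)]
        x = np.arange(10, dtype=float) + 1
        v = correlate_pair("GA|GB", "GA", "GB", self.expr(x, 100 - x, libs), libs,
                           "no_overlap", log_transform=False)
        assert v.r == pytest.approx(-1.0) and v.klass == "negative"

    def test_zero_variance_is_ns_with_undefined_r(self):
        libs = [f"L{i}" for i in range(5)]
        v = correlate_pair("GA|GB", "GA", "GB",
                           self.expr(np.ones(5), np.arange(5.0), libs), libs, "overlap")
        assert v.klass == "ns" and np.isnan(v.r)

    def test_r_matches_definition_oracle_small_n(self):
        rng = np.random.default_rng(9)
        for n in range(3, 21):
            libs = [f"L{i}" for i in range(n)]
            a, b = rng.normal(size=n) ** 2 + 1, rng.normal(size=n) ** 2 + 1
            v = correlate_pair("GA|GB", "GA", "GB", self.expr(a, b, libs), libs,
                               "overlap", log_transform=False)
            assert v.r == pytest.approx(pearson_oracle(a, b), abs=1e-10)

    def test_sign_recovery_under_planted_correlation(self):
        """Planted rho = 0.8 at n = 15: the sign is recovered in >= 95%
        of 500 replicates."""
        rng = np.random.default_rng(45)
        libs = [f"L{i}" for i in range(15)]
        ok = 0
        for _ in range(500):
            z = rng.normal(size=15)
            a = np.sqrt(0.8) * z + np.sqrt(0.2) * rng.normal(size=15)
            b = np.sqrt(0.8) * z + np.sqrt(0.2) * rng.normal(size=15)
            v = correlate_pair("GA|GB", "GA", "GB",
                               self.expr(2.0**a, 2.0**b, libs), libs, "overlap")
            ok += v.r > 0
        assert ok / 500 >= 0.95


class TestPairedTest:
    def test_identical_means_give_t_zero_p_one(self):
        libs = ["O1", "O2", "N1", "N2"]
        expr = pd.DataFrame(
            [[4, 4, 4, 4], [8, 8, 8, 8]], index=["GA", "GB"], columns=libs, dtype=float
        )
        cps = [ContrastPair("GA|GB", {"O1", "O2"}, {"N1", "N2"})]
        res = paired_overlap_test(cps, expr)
        assert res.t == pytest.approx(0.0) and res.p == pytest.approx(1.0)

    def test_constant_shift_detected_with_correct_sign(self):
        rng = np.random.default_rng(2)
        genes = [f"G{i}" for i in range(20)]
        base = rng.uniform(3, 8, size=20)
        expr = pd.DataFrame(
            {"O": 2.0 ** (base + 1.0) - 1, "N": 2.0**base - 1}, index=genes
        )
        cps = [ContrastPair(f"{genes[2*i]}|{genes[2*i+1]}", {"O"}, {"N"}) for i in range(10)]
        res = paired_overlap_test(cps, expr)
        assert res.t > 0 and res.p < 1e-6
        assert res.n_genes == 20

    def test_fewer_than_two_genes_errors(self):
        expr = pd.DataFrame({"O": [1.0], "N": [2.0]}, index=["GA"])
        with pytest.raises(ValueError):
            paired_overlap_test([ContrastPair("GA|GHOST", {"O"}, {"N"})], expr)


class TestGroupTests:
    def test_u_statistic_matches_pair_count_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            nx, ny = int(rng.integers(2, 21)), int(rng.integers(2, 21))
            x = rng.integers(0, 10, size=nx).astype(float)
            y = rng.integers(0, 10, size=ny).astype(float)
            u, _ = stats.mannwhitneyu(x, y, alternative="two-sided")
            assert u == pytest.approx(mann_whitney_u_oracle(x, y))

    def test_identical_groups_not_significant(self):
        counts = {(f"G{i}", "L1"): 1 + (i % 2) for i in range(40)}
        expr = pd.DataFrame({"L1": np.ones(40) * 7}, index=[f"G{i}" for i in range(40)])
        obs, tests = expression_by_tss_count(counts, expr)
        assert len(obs) == 40
        assert tests.loc[0, "p"] == pytest.approx(1.0)

    def test_shifted_groups_strongly_significant(self):
        rng = np.random.default_rng(19)
        genes = [f"G{i}" for i in range(400)]
        counts = {(g, "L1"): 1 + (i >= 200) for i, g in enumerate(genes)}
        vals = np.concatenate([2.0 ** rng.normal(4, 1, 200),
                               2.0 ** rng.normal(6, 1, 200)])  # 2 sigma shift
        expr = pd.DataFrame({"L1": vals}, index=genes)
        _, tests = expression_by_tss_count(counts, expr)
        assert tests.loc[0, "p"] < 1e-6

    def test_category_observations_partition(self):
        cats = pd.DataFrame(
            {
                "gene_id": ["A", "B", "C"],
                "library_id": ["L1"] * 3,
                "pair_id": ["A|B", "A|B", "C|D"],
                "category": ["overlap_multi", "overlap_single", "single_expressed_single"],
            }
        )
        expr = pd.DataFrame({"L1": [4.0, 2.0, 8.0]}, index=["A", "B", "C"])
        obs, tests = expression_by_category(cats, expr)
        assert len(obs) == 3 and obs["category"].value_counts().sum() == 3

    def test_planted_multi_uplift_detected_within_arm(self):
        rng = np.random.default_rng(29)
        rows, vals = [], []
        for i in range(300):
            multi = i % 2 == 0
            rows.append(
                {"gene_id": f"G{i}", "library_id": "L1", "pair_id": f"P{i}",
                 "category": "overlap_multi" if multi else "overlap_single"}
            )
            vals.append(2.0 ** rng.normal(6 if multi else 4, 1))
        cats = pd.DataFrame(rows)
        expr = pd.DataFrame({"L1": vals}, index=[f"G{i}" for i in range(300)])
        obs, tests = expression_by_category(cats, expr)
        row = tests[(tests["category_a"] == "overlap_multi")
                    & (tests["category_b"] == "overlap_single")]
        assert float(row["p"].iloc[0]) < 1e-6
        multi_mean = obs[obs["category"] == "overlap_multi"]["expression"].mean()
        single_mean = obs[obs["category"] == "overlap_single"]["expression"].mean()
        assert multi_mean > single_mean
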