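"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity from first principles — explicit base
sets, exhaustive enumeration, literal predicate re-evaluation — without
touching the implementation paths it checks.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

from tssoverlap.models import GeneModel, TssRecord


def overlap_oracle(
    gene_plus: GeneModel,
    gene_minus: GeneModel,
    positions_plus: list[int],
    positions_minus: list[int],
) -> tuple[str, int]:
    """Verdict and overlap length by materialising explicit base sets.

    The plus gene occupies every base from its most upstream TSS to its
    annotated 3' end; the minus gene from its annotated 3' end to its
    most upstream TSS.  The pair overlaps when each 5' end is a member
    of the partner's base set; the length is the size of the
    intersection.
    """
    if not positions_plus and not positions_minus:
        return "none_expressed", 0
    if not positions_plus or not positions_minus:
        return "single_expressed", 0
    a = min(positions_plus)
    b = max(positions_minus)
    plus_bases = set(range(a, gene_plus.span_end))
    minus_bases = set(range(gene_minus.span_start, b + 1))
    if a in minus_bases and b in plus_bases:
        return "overlap", len(plus_bases & minus_bases)
    return "no_overlap", 0


def filter_oracle(record: TssRecord, gene: GeneModel, min_ppm, max_dist, require_confident) -> bool:
    """Literal re-evaluation of the three admission predicates."""
    if require_confident and not record.confident:
        return False
    if record.expression_ppm < min_ppm:
        return False
    if abs(record.position - gene.annotated_five_prime) > max_dist:
        return False
    return True


def snp_class_oracle(ref: int, alt: int) -> str:
    """Exact-arithmetic interval test on the minor-allele fraction."""
    f = Fraction(min(ref, alt), ref + alt)
    if f < Fraction(2, 100):
        return "monoallelic"
    if f < Fraction(20, 100):
        return "skewed"
    return "biallelic"


def pearson_oracle(x, y) -> float:
    """Sample Pearson coefficient from its definition."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


def mann_whitney_u_oracle(x, y) -> float:
    """U statistic as the explicit count of concordant pairs (ties 0.5)."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def hypergeom_tail_oracle(k: int, M: int, n: int, N: int) -> float:
    """P(X >= k) by direct summation of hypergeometric point masses."""
    from math import comb

    total = comb(M, N)
    return sum(comb(n, i) * comb(M - n, N - i) for i in range(k, min(n, N) + 1)) / total


def pwm_window_oracle(seq: str, matrix: np.ndarray) -> list[float | None]:
    """Score every window by an independent per-position sum (None if N)."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = matrix.shape[1]
    out = []
    for i in range(len(seq) - L + 1):
        window = seq[i : i + L]
        if any(ch not in idx for ch in window):
            out.append(None)
            continue
        out.append(sum(matrix[idx[ch], j] for j, ch in enumerate(window)))
    return out


def random_pair_config(rng: np.random.Generator):
    """One randomised head-to-head gene/TSS configuration (genes <= 10 kb,
    <= 5 TSSs per gene) for the overlap oracle comparison."""
    from tssoverlap.models import GenePair

    anchor = int(rng.integers(20_000, 40_000))
    len_p = int(rng.integers(200, 10_000))
    len_m = int(rng.integers(200, 10_000))
    start_p = anchor + int(rng.integers(-3_000, 3_000))
    end_m = anchor + int(rng.integers(-3_000, 3_000))
    gp = GeneModel("GP", "chr1", "+", start_p, start_p + len_p)
    gm = GeneModel("GM", "chr1", "-", max(0, end_m - len_m), end_m + 1)
    pair = GenePair("GP|GM", "GP", "GM", "chr1")

    def tss_positions(gene: GeneModel) -> list[int]:
        n = int(rng.integers(0, 6))
        return [
            int(gene.annotated_five_prime + rng.integers(-5_000, 5_001))
            for _ in range(n)
        ]

    return pair, gp, gm, tss_positions(gp), tss_positions(gm)


def make_records(gene: GeneModel, library: str, positions: list[int]) -> list[TssRecord]:
    return [
        TssRecord(gene.gene_id, library, gene.chrom, gene.strand, p, 10.0)
        for p in positions
    ]
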