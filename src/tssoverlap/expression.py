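"""Overlap-stratified expression statistics.

Covers the contrast-pair selection (pairs overlapping in at least
``min_each`` libraries and not overlapping in at least ``min_each``
others), per-pair Pearson correlation within each stratum, the paired
t-test comparing per-gene mean expression between overlap and
non-overlap libraries, and TSS-count / six-category group comparisons
with Mann–Whitney U tests.

Expression values are log-transformed (log2(x + 1)) before the
correlation and t-test by default — expression is heavy-tailed and the
paired t-test assumes an additive shift on a roughly symmetric scale; a
raw-scale mode is available via ``log_transform=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import PairLibraryStatus

DEFAULT_MIN_EACH = 10
DEFAULT_ALPHA = 0.05


@dataclass
class ContrastPair:
    pair_id: str
    libs_overlap: set[str]
    libs_no_overlap: set[str]


@dataclass
class CorrelationVerdict:
    pair_id: str
    stratum: str  # "overlap" or "no_overlap"
    r: float
    p: float
    klass: str  # "positive", "negative", "ns"
    n: int


def _maybe_log(values: np.ndarray, log_transform: bool) -> np.ndarray:
    return np.log2(values + 1.0) if log_transform else values


def select_contrast_pairs(
    statuses: Sequence[PairLibraryStatus], min_each: int = DEFAULT_MIN_EACH
) -> list[ContrastPair]:
    """Pairs with >= min_each overlap libraries and >= min_each
    no-overlap libraries (both genes expressed in every listed library)."""
    libs: dict[str, dict[str, set[str]]] = {}
    for s in statuses:
        if s.state in ("overlap", "no_overlap"):
            libs.setdefault(s.pair_id, {"overlap": set(), "no_overlap": set()})[
                s.state
            ].add(s.library_id)
    out = []
    for pair_id in sorted(libs):
        d = libs[pair_id]
        if len(d["overlap"]) >= min_each and len(d["no_overlap"]) >= min_each:
            out.append(ContrastPair(pair_id, d["overlap"], d["no_overlap"]))
    return out


def correlate_pair(
    pair_id: str,
    gene_a: str,
    gene_b: str,
    expression: pd.DataFrame,
    stratum_libs: Sequence[str],
    stratum: str,
    alpha: float = DEFAULT_ALPHA,
    log_transform: bool = True,
) -> CorrelationVerdict:
    """Pearson correlation of the two genes' expression across the
    stratum's libraries, classed positive / negative / ns at ``alpha``.

    ``expression`` is genes x libraries.  A gene with zero variance in
    the stratum yields an undefined r reported as ns.
    """
    libs = sorted(stratum_libs)
    if len(libs) < 3:
        raise ValueError("need at least 3 libraries for a correlation")
    x = _maybe_log(expression.loc[gene_a, libs].to_numpy(dtype=float), log_transform)
    y = _maybe_log(expression.loc[gene_b, libs].to_numpy(dtype=float), log_transform)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationVerdict(pair_id, stratum, float("nan"), float("nan"), "ns", len(libs))
    r, p = stats.pearsonr(x, y)
    if p <= alpha and r > 0:
        klass = "positive"
    elif p <= alpha and r < 0:
        klass = "negative"
    else:
        klass = "ns"
    return CorrelationVerdict(pair_id, stratum, float(r), float(p), klass, len(libs))


def correlate_contrast_pairs(
    pairs: Sequence[ContrastPair],
    expression: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Correlation verdicts for every contrast pair in both strata."""
    rows = []
    for cp in pairs:
        ga, gb = cp.pair_id.split("|")
        for stratum, libs in (("overlap", cp.libs_overlap), ("no_overlap", cp.libs_no_overlap)):
            v = correlate_pair(cp.pair_id, ga, gb, expression, sorted(libs), stratum, alpha, log_transform)
            rows.append(
                {
                    "pair_id": v.pair_id,
                    "stratum": v.stratum,
                    "r": v.r,
                    "p": v.p,
                    "class": v.klass,
                    "n_libraries": v.n,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PairedTestResult:
    t: float
    p: float
    n_genes: int
    mean_overlap: float
    mean_no_overlap: float
    per_gene: pd.DataFrame


def paired_overlap_test(
    contrast_pairs: Sequence[ContrastPair],
    expression: pd.DataFrame,
    log_transform: bool = True,
) -> PairedTestResult:
    """Paired t-test of per-gene mean expression, overlap vs no-overlap.

    The unit of pairing is the gene: for each gene of each contrast
    pair, its mean expression over the pair's overlap libraries is
    paired with its mean over the no-overlap libraries.
    """
    rows = []
    for cp in contrast_pairs:
        for gene in cp.pair_id.split("|"):
            if gene not in expression.index:
                continue
            ov = _maybe_log(
                expression.loc[gene, sorted(cp.libs_overlap)].to_numpy(dtype=float), log_transform
            ).mean()
            no = _maybe_log(
                expression.loc[gene, sorted(cp.libs_no_overlap)].to_numpy(dtype=float), log_transform
            ).mean()
            rows.append({"gene_id": gene, "pair_id": cp.pair_id, "mean_overlap": ov, "mean_no_overlap": no})
    per_gene = pd.DataFrame(rows)
    if len(per_gene) < 2:
        raise ValueError("need at least 2 genes with defined means for the paired test")
    diffs = (per_gene["mean_overlap"] - per_gene["mean_no_overlap"]).to_numpy()
    if np.ptp(diffs) == 0:
        # degenerate: identical differences for every gene
        if diffs[0] == 0:
            t, p = 0.0, 1.0
        else:
            t, p = np.sign(diffs[0]) * np.inf, 0.0
    else:
        t, p = stats.ttest_rel(per_gene["mean_overlap"], per_gene["mean_no_overlap"])
    return PairedTestResult(
        t=float(t),
        p=float(p),
        n_genes=len(per_gene),
        mean_overlap=float(per_gene["mean_overlap"].mean()),
        mean_no_overlap=float(per_gene["mean_no_overlap"].mean()),
        per_gene=per_gene,
    )


def _adjacent_mwu(groups: dict, observations: Mapping) -> pd.DataFrame:
    keys = sorted(groups)
    rows = []
    for k1, k2 in zip(keys, keys[1:]):
        a, b = groups[k1], groups[k2]
        if len(a) == 0 or len(b) == 0:
            continue
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"group_low": k1, "group_high": k2, "U": float(u), "p": float(p)})
    return pd.DataFrame(rows, columns=["group_low", "group_high", "U", "p"])


def expression_by_tss_count(
    tss_counts: Mapping[tuple[str, str], int],
    expression: pd.DataFrame,
    max_bin: int = 4,
    log_transform: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression distributions grouped by per-library TSS count.

    Observations are (gene, library) pairs with >= 1 admitted TSS;
    counts above ``max_bin`` collapse into the top bin.  Returns the
    long-format observation table and two-sided Mann–Whitney U tests
    between adjacent count groups.
    """
    rows = []
    for (gene, lib), n in tss_counts.items():
        if n < 1 or gene not in expression.index or lib not in expression.columns:
            continue
        val = float(expression.loc[gene, lib])
        if log_transform:
            val = float(np.log2(val + 1.0))
        rows.append({"gene_id": gene, "library_id": lib, "n_tss": min(int(n), max_bin), "expression": val})
    obs = pd.DataFrame(rows, columns=["gene_id", "library_id", "n_tss", "expression"])
    groups = {k: g["expression"].to_numpy() for k, g in obs.groupby("n_tss")}
    return obs, _adjacent_mwu(groups, tss_counts)


def expression_by_category(
    categories: pd.DataFrame,
    expression: pd.DataFrame,
    log_transform: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression by six-way organization x TSS-count category.

    ``categories`` is the frame from
    :func:`tssoverlap.overlap.gene_category_frame`.  Returns the
    observation table and the full pairwise Mann–Whitney matrix (long
    format) over nonempty categories.
    """
    rows = []
    for r in categories.itertuples(index=False):
        if r.gene_id not in expression.index or r.library_id not in expression.columns:
            continue
        val = float(expression.loc[r.gene_id, r.library_id])
        if log_transform:
            val = float(np.log2(val + 1.0))
        rows.append(
            {"gene_id": r.gene_id, "library_id": r.library_id, "category": r.category, "expression": val}
        )
    obs = pd.DataFrame(rows, columns=["gene_id", "library_id", "category", "expression"])
    groups = {k: g["expression"].to_numpy() for k, g in obs.groupby("category")}
    names = sorted(groups)
    tests = []
    for i, c1 in enumerate(names):
        for c2 in names[i + 1 :]:
            u, p = stats.mannwhitneyu(groups[c1], groups[c2], alternative="two-sided")
            tests.append({"category_a": c1, "category_b": c2, "U": float(u), "p": float(p)})
    return obs, pd.DataFrame(tests, columns=["category_a", "category_b", "U", "p"])
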