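"""Ternary overlap matrix, Ward clustering and local gene-set enrichment.

Each (pair, library) cell takes 1 when the pair used overlapping TSSs,
0.5 when there was expression without overlap (either one or both genes
expressed), and 0 when neither gene was expressed.  Only pairs that
overlap in at least one library are kept as rows.  Libraries and pairs
are clustered hierarchically with Ward linkage on Euclidean distances.

Enrichment of a query gene list against reference sets is a one-sided
hypergeometric test with Benjamini–Hochberg correction; sets sharing
fewer than ``min_overlap`` genes with the query are dropped before
testing, and results are reported with their -log10 transforms and
sorted by their sum, mirroring how enrichment tables are customarily
assembled for such screens.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .models import PairLibraryStatus

STATE_TO_CELL = {
    "overlap": 1.0,
    "no_overlap": 0.5,
    "single_expressed": 0.5,
    "none_expressed": 0.0,
}

DEFAULT_MIN_OVERLAP = 4


def build_overlap_matrix(statuses: Sequence[PairLibraryStatus]) -> pd.DataFrame:
    """Pairs x libraries matrix over {0, 0.5, 1}.

    Rows without any 1 (pairs never overlapping) are excluded; the
    result is a pure function of the statuses.
    """
    df = pd.DataFrame(
        {
            "pair_id": [s.pair_id for s in statuses],
            "library_id": [s.library_id for s in statuses],
            "cell": [STATE_TO_CELL[s.state] for s in statuses],
        }
    )
    mat = df.pivot_table(index="pair_id", columns="library_id", values="cell", fill_value=0.0)
    mat = mat.loc[(mat == 1.0).any(axis=1)]
    mat = mat.sort_index(axis=0).sort_index(axis=1)
    return mat


@dataclass
class ClusterResult:
    row_order: list[str]
    col_order: list[str]
    row_labels: pd.Series  # flat cluster label per pair at the requested cut
    col_labels: pd.Series  # flat cluster label per library
    row_linkage: np.ndarray
    col_linkage: np.ndarray


def cluster_bidirectional(
    matrix: pd.DataFrame, n_row_clusters: int = 3, n_col_clusters: int = 3
) -> ClusterResult:
    """Ward clustering of both pairs (rows) and libraries (columns).

    Deterministic given the input; a single row or column yields a
    degenerate single-leaf result.  Flat labels come from cutting each
    dendrogram into the requested number of clusters.
    """
    if matrix.empty:
        raise ValueError("cannot cluster an empty matrix")

    def one_axis(data: np.ndarray, names: list[str], k: int):
        if len(names) == 1:
            return names, pd.Series([1], index=names), np.empty((0, 4))
        link = hierarchy.ward(pdist(data, metric="euclidean"))
        order = [names[i] for i in hierarchy.leaves_list(link)]
        labels = hierarchy.fcluster(link, t=min(k, len(names)), criterion="maxclust")
        return order, pd.Series(labels, index=names), link

    rows = list(matrix.index)
    cols = list(matrix.columns)
    row_order, row_labels, row_link = one_axis(matrix.to_numpy(), rows, n_row_clusters)
    col_order, col_labels, col_link = one_axis(matrix.to_numpy().T, cols, n_col_clusters)
    return ClusterResult(row_order, col_order, row_labels, col_labels, row_link, col_link)


@dataclass
class EnrichmentResult:
    set_name: str
    overlap_count: int
    p_value: float
    fdr: float

    @property
    def minus_log10_p(self) -> float:
        return -np.log10(max(self.p_value, np.finfo(float).tiny))

    @property
    def minus_log10_fdr(self) -> float:
        return -np.log10(max(self.fdr, np.finfo(float).tiny))


def enrich(
    query_genes: Iterable[str],
    reference_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric enrichment of a query list.

    P(X >= k) for k query genes in a reference set, drawing |query|
    genes from a universe of size M containing |set| successes.  Sets
    overlapping the query in fewer than ``min_overlap`` genes are
    dropped before testing; BH-FDR is computed over the reported sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes) & universe
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")

    rows = []
    for name, members in reference_sets.items():
        members = set(members) & universe
        k = len(query & members)
        if k < min_overlap:
            continue
        p = float(hypergeom.sf(k - 1, len(universe), len(members), len(query)))
        rows.append((name, k, p))
    if not rows:
        return []
    pvals = [p for _, _, p in rows]
    fdr = multipletests(pvals, method="fdr_bh")[1]
    results = [
        EnrichmentResult(set_name=n, overlap_count=k, p_value=p, fdr=float(q))
        for (n, k, p), q in zip(rows, fdr)
    ]
    results.sort(key=lambda r: r.minus_log10_p + r.minus_log10_fdr, reverse=True)
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "overlap_count": r.overlap_count,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "minus_log10_p": r.minus_log10_p,
                "minus_log10_fdr": r.minus_log10_fdr,
            }
            for r in results
        ]
    )
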