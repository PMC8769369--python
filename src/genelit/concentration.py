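"""Concentration of early-stage research on a handful of recent gene targets.

Within a study period, the eligible genes are those that occupy the *recent*
class (first highlighted 1-5 years earlier) for at least one year of the
period — time windows are allowed to overlap and shift, so a gene first
highlighted five years before the period starts is still eligible for its
final recent year.  Genes are ranked by the number of publications
highlighting them while recent; the cumulative pair share over ranks, the top
1% gene set and its pair share, per-journal top-set shares, the journal x
gene percentage matrix with Ward clustering, and the top-set ablation re-test
quantify how concentrated the follow-up interest is.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, to_tree, ward
from scipy.spatial.distance import pdist

from . import context_enrich
from .gene_age import RECENT_MAX_AGE

__all__ = [
    "rank_recent_targets",
    "top_set",
    "journal_topk_share",
    "build_journal_gene_matrix",
    "ward_cluster",
    "ablation_retest",
    "top_set_size",
]


def _eligible_genes(age_table: pd.DataFrame, period: tuple[int, int]) -> pd.Index:
    start, end = period
    first = age_table["first_year"]
    return age_table.index[(first >= start - RECENT_MAX_AGE) & (first <= end - 1)]


def _recent_pairs_in_period(pairs_with_class: pd.DataFrame,
                            period: tuple[int, int]) -> pd.DataFrame:
    start, end = period
    return pairs_with_class[
        pairs_with_class["pub_year"].between(start, end)
        & (pairs_with_class["age_class"] == "recent")]


def rank_recent_targets(
    pairs_with_class: pd.DataFrame,
    age_table: pd.DataFrame,
    period: tuple[int, int],
) -> pd.DataFrame:
    """Rank eligible genes by recent-pair count within the period.

    Rank 0 is the most-published gene; ties break by gene_id ascending for
    determinism.  Eligible genes with zero recent pairs in the period are
    included (they were available for follow-up but never taken up).  The
    cumulative share reaches exactly 1 at the last rank.
    """
    start, end = period
    if start > end:
        raise ValueError(f"empty period {period}")
    eligible = _eligible_genes(age_table, period)
    recent = _recent_pairs_in_period(pairs_with_class, period)
    counts = recent.groupby("gene_id").size()
    table = pd.DataFrame({"gene_id": eligible})
    table["n_recent_pairs"] = table["gene_id"].map(counts).fillna(0).astype(int)
    table = table.sort_values(["n_recent_pairs", "gene_id"],
                              ascending=[False, True]).reset_index(drop=True)
    table["rank"] = np.arange(len(table))
    total = table["n_recent_pairs"].sum()
    if total > 0:
        table["cum_share"] = table["n_recent_pairs"].cumsum() / total
    else:
        table["cum_share"] = np.nan
    return table


def top_set_size(n_eligible: int, fraction: float = 0.01) -> int:
    """Number of genes in the top set: ceil(fraction x eligible genes)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    return math.ceil(fraction * n_eligible)


def top_set(rank_table: pd.DataFrame, fraction: float = 0.01) -> tuple[list, float]:
    """The top-ranked genes (ceil of the eligible-gene fraction) and their
    combined share of recent pairs."""
    k = top_set_size(len(rank_table), fraction)
    top = rank_table.head(k)
    total = rank_table["n_recent_pairs"].sum()
    share = float(top["n_recent_pairs"].sum() / total) if total > 0 else float("nan")
    return top["gene_id"].tolist(), share


def journal_topk_share(
    pairs_with_class: pd.DataFrame,
    records: pd.DataFrame,
    journals: Sequence[str],
    top_genes: Sequence[str],
    period: tuple[int, int],
) -> pd.Series:
    """Per-journal percentage of its recent-target pairs that fall on the top
    gene set.  Journals with no recent pairs in the period are absent."""
    recent = _recent_pairs_in_period(pairs_with_class, period)
    journal_of = records.set_index("pmid")["journal"]
    recent = recent.assign(journal=recent["pmid"].map(journal_of))
    recent = recent[recent["journal"].isin(set(journals))]
    top = set(top_genes)
    out = {}
    for journal, sub in recent.groupby("journal"):
        out[journal] = 100.0 * sub["gene_id"].isin(top).mean()
    return pd.Series(out, name="pct_on_top_genes")


def build_journal_gene_matrix(
    pairs_with_class: pd.DataFrame,
    records: pd.DataFrame,
    journals: Sequence[str],
    genes: Sequence[str],
    period: tuple[int, int],
) -> pd.DataFrame:
    """Journal x gene matrix: percentage of the journal's period publications
    highlighting the gene while it was recent.

    The denominator is all of the journal's publications in the period within
    the corpus passed in; rows can sum past 100 when publications highlight
    several of the genes.  Journals with no publications in the period are
    omitted.
    """
    start, end = period
    in_period = records[records["year"].between(start, end)]
    totals = in_period.groupby("journal")["pmid"].nunique()
    recent = _recent_pairs_in_period(pairs_with_class, period)
    journal_of = records.set_index("pmid")["journal"]
    recent = recent.assign(journal=recent["pmid"].map(journal_of))
    recent = recent[recent["gene_id"].isin(set(genes))]
    counts = (recent.groupby(["journal", "gene_id"])["pmid"].nunique()
              .unstack(fill_value=0))
    rows = [j for j in journals if totals.get(j, 0) > 0]
    matrix = counts.reindex(index=rows, columns=list(genes), fill_value=0).fillna(0)
    return 100.0 * matrix.div(totals.reindex(rows), axis=0)


def _linkage_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    tree = to_tree(linkage)

    def render(node) -> str:
        if node.is_leaf():
            return str(labels[node.id])
        return (f"({render(node.left)}:{node.dist - node.left.dist:.6g},"
                f"{render(node.right)}:{node.dist - node.right.dist:.6g})")

    return render(tree) + ";"


def ward_cluster(matrix: pd.DataFrame) -> dict:
    """Ward minimum-variance clustering of rows and columns independently
    (Euclidean distances on the raw percentage cells).

    Returns row/column orders (leaf order, deterministic for a given input
    order), the two linkage matrices, and Newick renderings of the trees.
    Degenerate inputs (<2 rows or columns) keep the identity ordering.
    """
    if not np.isfinite(matrix.to_numpy(dtype=float)).all():
        raise ValueError("matrix must be finite")
    out = {"row_labels": list(matrix.index), "col_labels": list(matrix.columns),
           "row_order": list(matrix.index), "col_order": list(matrix.columns),
           "row_linkage": None, "col_linkage": None,
           "row_newick": None, "col_newick": None}
    if matrix.shape[0] >= 2:
        z = ward(pdist(matrix.to_numpy(dtype=float)))
        order = leaves_list(z)
        out["row_linkage"] = z
        out["row_order"] = [matrix.index[i] for i in order]
        out["row_newick"] = _linkage_newick(z, list(matrix.index))
    if matrix.shape[1] >= 2:
        z = ward(pdist(matrix.to_numpy(dtype=float).T))
        order = leaves_list(z)
        out["col_linkage"] = z
        out["col_order"] = [matrix.columns[i] for i in order]
        out["col_newick"] = _linkage_newick(z, list(matrix.columns))
    return out


def ablation_retest(
    pairs_with_class: pd.DataFrame,
    records: pd.DataFrame,
    membership: pd.DataFrame,
    top_genes: Sequence[str],
    period: tuple[int, int],
    alpha: float = 0.01,
    min_group_size: int = 1,
) -> pd.DataFrame:
    """Re-run the recent-target enrichment scan with the top genes removed.

    Returns the scan restricted to groups that remain significantly enriched;
    with an empty top set this reduces to the original scan's enriched set.
    """
    start, end = period
    kept = pairs_with_class[~pairs_with_class["gene_id"].isin(set(top_genes))]
    kept = kept[kept["pub_year"].between(start, end)]
    corpus = set(records.loc[records["year"].between(start, end), "pmid"])
    if len(kept) == 0:
        return pd.DataFrame(columns=["group", "a", "b", "c", "d", "log2_fold",
                                     "p_raw", "significant", "direction"])
    targets = context_enrich.target_publications(kept, "recent")
    scan = context_enrich.enrichment_scan(corpus, targets, membership,
                                          alpha=alpha, min_group_size=min_group_size)
    return scan[scan["direction"] == "enriched"].reset_index(drop=True)
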