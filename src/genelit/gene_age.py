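"""Gene ages: first-highlight years, age classes, and the temporal series.

A gene's *age* at a given publication is the number of calendar years since
the gene was first highlighted anywhere in the corpus.  Ages partition pairs
into three classes:

* ``new``    — age 0 (first highlighted in the publication's own year),
* ``recent`` — age 1 to 5,
* ``old``    — age 6 or more.

A publication inherits the *youngest* class among the genes it highlights, so
one never-before-seen gene makes the whole publication "new".  Publications
highlighting at least one new or recent gene constitute early-stage research.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .stats_core import BootstrapCI, bootstrap_ci

__all__ = [
    "AGE_CLASSES",
    "DEFAULT_DECADES",
    "age_class",
    "first_highlight_years",
    "assign_age_classes",
    "publication_age_class",
    "cumulative_highlight_curve",
    "pair_share_series",
    "category_enrichment_series",
    "decade_aggregate",
]

AGE_CLASSES = ("new", "recent", "old")
RECENT_MAX_AGE = 5

#: decade bins; the last period is truncated at the analysis end year
DEFAULT_DECADES = ((1970, 1979), (1980, 1989), (1990, 1999), (2000, 2009),
                   (2010, 2018))


def age_class(pub_year: int, first_year: int) -> str:
    """Class of a single (publication year, first-highlight year) pair."""
    age = pub_year - first_year
    if age < 0:
        raise ValueError(
            f"publication year {pub_year} precedes first highlight {first_year}")
    if age == 0:
        return "new"
    if age <= RECENT_MAX_AGE:
        return "recent"
    return "old"


def _classify_ages(ages: np.ndarray) -> np.ndarray:
    out = np.where(ages == 0, "new", np.where(ages <= RECENT_MAX_AGE, "recent", "old"))
    return out


def first_highlight_years(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-gene year of first highlight (and of first title mention).

    Returns a frame indexed by gene_id with columns ``first_year`` and
    ``first_year_title`` (NaN for genes never mentioned in a title).
    """
    first = pairs.groupby("gene_id")["pub_year"].min().rename("first_year")
    title_first = (
        pairs[pairs["in_title"]].groupby("gene_id")["pub_year"].min()
        .rename("first_year_title")
    )
    table = pd.concat([first, title_first], axis=1)
    table.index.name = "gene_id"
    return table


def assign_age_classes(pairs: pd.DataFrame, age_table: pd.DataFrame) -> pd.DataFrame:
    """Annotate each pair with the gene's first year, age and age class."""
    out = pairs.copy()
    out["first_year"] = out["gene_id"].map(age_table["first_year"]).astype(int)
    out["age"] = out["pub_year"] - out["first_year"]
    if (out["age"] < 0).any():
        raise ValueError("pair published before its gene's first highlight year")
    out["age_class"] = _classify_ages(out["age"].to_numpy())
    return out


def publication_age_class(pairs_with_class: pd.DataFrame) -> pd.Series:
    """Youngest-class rule: per publication, new > recent > old precedence."""
    rank = pairs_with_class["age_class"].map({"new": 0, "recent": 1, "old": 2})
    best = rank.groupby(pairs_with_class["pmid"]).min()
    return best.map({0: "new", 1: "recent", 2: "old"}).rename("pub_class")


def cumulative_highlight_curve(
    age_table: pd.DataFrame,
    registry: pd.DataFrame,
    years: Sequence[int],
    taxon: int = 9606,
    gene_subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Share of protein-coding genes ever highlighted (and ever title-mentioned)
    by each year.  Optionally restricted to a gene subset, e.g. loss-of-function
    intolerant genes."""
    eligible = registry[(registry["tax_id"] == taxon)
                        & (registry["gene_type"] == "protein-coding")]
    if gene_subset is not None:
        eligible = eligible[eligible["gene_id"].isin(set(gene_subset))]
    n = len(eligible)
    if n == 0:
        raise ValueError("empty gene registry after restriction")
    ages = age_table[age_table.index.isin(set(eligible["gene_id"]))]
    first = np.sort(ages["first_year"].to_numpy())
    first_title = np.sort(ages["first_year_title"].dropna().to_numpy())
    years = np.asarray(sorted(years))
    return pd.DataFrame({
        "year": years,
        "share_highlighted": np.searchsorted(first, years, side="right") / n,
        "share_title": np.searchsorted(first_title, years, side="right") / n,
    })


def _window_centers(years: pd.Series, window: int) -> list[int]:
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and positive, got {window}")
    return list(range(int(years.min()), int(years.max()) + 1))


def _class_share_matrix(window_pairs: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Per-publication counts of pairs in each age class (rows = publications)."""
    counts = (
        window_pairs.pivot_table(index="pmid", columns="age_class",
                                 values="gene_id", aggfunc="count", fill_value=0)
        .reindex(columns=AGE_CLASSES, fill_value=0)
    )
    return counts.to_numpy(dtype=float), list(counts.index)


def pair_share_series(
    pairs_with_class: pd.DataFrame,
    window: int = 3,
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Sliding-window share of pairs per age class, with bootstrap CIs.

    For each center year, pairs from the ``window``-year span around it are
    pooled; the three class shares sum to 1.  The bootstrap resamples
    publications.
    """
    half = window // 2
    rows = []
    for center in _window_centers(pairs_with_class["pub_year"], window):
        wp = pairs_with_class[
            pairs_with_class["pub_year"].between(center - half, center + half)]
        if len(wp) == 0:
            continue
        mat, _ = _class_share_matrix(wp)
        shares = mat.sum(axis=0) / mat.sum()
        for k, cls in enumerate(AGE_CLASSES):
            ci = bootstrap_ci(
                mat, statistic=lambda rows_, k=k: rows_[:, k].sum() / max(rows_.sum(), 1.0),
                level=level, n_boot=n_boot, seed=seed + center)
            rows.append({"center_year": center, "age_class": cls,
                         "share": shares[k], "lo": ci.lo, "hi": ci.hi})
    return pd.DataFrame(rows)


def _expected_class_weights(
    age_table: pd.DataFrame,
    years: Sequence[int],
    weights: pd.Series | None,
) -> np.ndarray:
    """Weighted share of genes per class, averaged over the window years.

    A gene contributes, in each calendar year of the window, to the class it
    occupies that year; genes not yet highlighted contribute nowhere.
    """
    first = age_table["first_year"]
    if weights is None:
        w = pd.Series(1.0, index=first.index)
    else:
        w = weights.reindex(first.index).fillna(0.0)
        if (w < 0).any():
            raise ValueError("gene weights must be non-negative")
    shares = np.zeros((len(years), 3))
    for i, y in enumerate(years):
        ages = y - first
        live = ages >= 0
        if not live.any():
            continue
        cls = _classify_ages(ages[live].to_numpy())
        wl = w[live].to_numpy()
        tot = wl.sum()
        if tot == 0:
            raise ValueError("all-zero gene weights in window")
        for k, c in enumerate(AGE_CLASSES):
            shares[i, k] = wl[cls == c].sum() / tot
    return shares.mean(axis=0)


def category_enrichment_series(
    pairs_with_class: pd.DataFrame,
    age_table: pd.DataFrame,
    weights: pd.Series | None = None,
    window: int = 3,
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """log2 enrichment of observed pair shares over gene-count expectation.

    enrichment = log2(observed pair share / expected share), where the
    expected share is the (optionally weighted) share of genes occupying the
    class, evaluated per calendar year of the window and averaged.  Observed 0
    with positive expectation yields -inf (reported, CI absent); zero
    expectation yields NaN.  Invariant under uniform rescaling of the weights.
    """
    half = window // 2
    rows = []
    for center in _window_centers(pairs_with_class["pub_year"], window):
        span = [y for y in range(center - half, center + half + 1)]
        wp = pairs_with_class[pairs_with_class["pub_year"].between(span[0], span[-1])]
        if len(wp) == 0:
            continue
        mat, _ = _class_share_matrix(wp)
        observed = mat.sum(axis=0) / mat.sum()
        expected = _expected_class_weights(age_table, span, weights)
        for k, cls in enumerate(AGE_CLASSES):
            if expected[k] == 0:
                enr, lo, hi = np.nan, np.nan, np.nan
            elif observed[k] == 0:
                enr, lo, hi = -np.inf, np.nan, np.nan
            else:
                enr = float(np.log2(observed[k] / expected[k]))
                ci = bootstrap_ci(
                    mat,
                    statistic=lambda rows_, k=k: rows_[:, k].sum() / max(rows_.sum(), 1.0),
                    level=level, n_boot=n_boot, seed=seed + center)
                lo = float(np.log2(ci.lo / expected[k])) if ci.lo > 0 else -np.inf
                hi = float(np.log2(ci.hi / expected[k])) if ci.hi > 0 else -np.inf
            rows.append({"center_year": center, "age_class": cls,
                         "enrichment": enr, "lo": lo, "hi": hi})
    return pd.DataFrame(rows)


def decade_aggregate(
    records: pd.DataFrame,
    pairs_with_class: pd.DataFrame,
    metric: str = "mean_authors",
    decades: Sequence[tuple[int, int]] = DEFAULT_DECADES,
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-(decade, publication class) team-size / gene-count aggregates.

    ``metric`` is one of ``mean_authors``, ``median_authors``, ``mean_genes``,
    ``median_genes``.  Each publication is classed by its youngest highlighted
    gene; the bootstrap resamples publications.  Empty cells are reported with
    NaN (not applicable).
    """
    agg, quantity = metric.split("_")
    if agg not in ("mean", "median") or quantity not in ("authors", "genes"):
        raise ValueError(f"unknown metric {metric!r}")
    pub_class = publication_age_class(pairs_with_class)
    if quantity == "authors":
        values = records.set_index("pmid")["n_authors"]
    else:
        values = pairs_with_class.groupby("pmid")["gene_id"].count()
    frame = pd.DataFrame({"value": values}).join(pub_class, how="inner")
    frame["year"] = frame.index.map(records.set_index("pmid")["year"])

    rows = []
    for (start, end) in decades:
        in_dec = frame[frame["year"].between(start, end)]
        for cls in AGE_CLASSES:
            cell = in_dec.loc[in_dec["pub_class"] == cls, "value"]
            if len(cell) == 0:
                rows.append({"decade": f"{start}-{end}", "age_class": cls,
                             "value": np.nan, "lo": np.nan, "hi": np.nan, "n": 0})
                continue
            ci = bootstrap_ci(cell.to_numpy(), statistic=agg, level=level,
                              n_boot=n_boot, seed=seed + start)
            rows.append({"decade": f"{start}-{end}", "age_class": cls,
                         "value": ci.point, "lo": ci.lo, "hi": ci.hi,
                         "n": len(cell)})
    return pd.DataFrame(rows)
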