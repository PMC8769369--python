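"""Citation-based reception metrics.

Works over a directed citation graph (citing -> cited) with per-node year and
publication-type metadata:

* within-year citation percentiles and the "highly cited" flag (top 5% of the
  publication-year cohort),
* citation-variability windows (IQR width of within-year percentiles),
* clinical-trial citation (whether and how soon a publication is cited by a
  clinical trial),
* the disruption index: among publications citing a focal paper or at least
  one of its references, (citers of focal only - citers of both) / all such
  citers.  +1 is maximally disruptive, -1 maximally consolidating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats_core import cohort_percentiles

__all__ = [
    "CitationGraph",
    "DisruptionResult",
    "load_citation_graph",
    "highly_cited_table",
    "is_clinical_trial",
    "clinical_citation_stats",
    "disruption_index",
    "disruption_table",
    "citation_variability",
]

HIGHLY_CITED_PERCENTILE = 95.0
LOW_COHORT_SIZE = 20


class CitationGraph:
    """Directed citation edges plus per-node metadata.

    ``nodes`` must carry pmid, year and publication_types; a citation_count
    column overrides the in-degree (it may include citations from
    publications outside the loaded edge list, which then contribute to
    percentiles but not to disruption classification).  Self-citation edges
    are dropped on construction.
    """

    def __init__(self, edges: pd.DataFrame, nodes: pd.DataFrame):
        edges = edges[edges["citing_pmid"] != edges["cited_pmid"]].copy()
        known = set(nodes["pmid"])
        referenced = set(edges["citing_pmid"]) | set(edges["cited_pmid"])
        missing = referenced - known
        if missing:
            raise ValueError(
                f"{len(missing)} pmid(s) in the edge list lack node metadata")
        self.edges = edges.reset_index(drop=True)
        self.nodes = nodes.set_index("pmid")
        if "citation_count" not in self.nodes.columns:
            indeg = edges.groupby("cited_pmid").size()
            self.nodes["citation_count"] = (
                self.nodes.index.map(indeg).fillna(0).astype(int))
        self._in: dict = {p: set() for p in self.nodes.index}
        self._out: dict = {p: set() for p in self.nodes.index}
        for citing, cited in zip(edges["citing_pmid"], edges["cited_pmid"]):
            self._in[cited].add(citing)
            self._out[citing].add(cited)

    def citers(self, pmid) -> set:
        return self._in.get(pmid, set())

    def references(self, pmid) -> set:
        return self._out.get(pmid, set())


def load_citation_graph(edges_path, records: pd.DataFrame,
                        citation_counts: pd.DataFrame | None = None) -> CitationGraph:
    """Build a graph from a citations.tsv edge list and the publication table.

    ``citation_counts`` optionally supplies (pmid, citation_count) totals that
    include out-of-graph citers.
    """
    edges = pd.read_csv(edges_path, sep="\t")
    nodes = records[["pmid", "year", "publication_types"]].copy()
    if citation_counts is not None:
        counts = citation_counts.set_index("pmid")["citation_count"]
        nodes["citation_count"] = nodes["pmid"].map(counts).fillna(0).astype(int)
    return CitationGraph(edges, nodes)


def highly_cited_table(graph: CitationGraph) -> pd.DataFrame:
    """Within-year citation percentile and top-5% flag for every node.

    Cohorts smaller than 20 publications still get a flag but are marked
    ``low_cohort``.
    """
    df = graph.nodes.reset_index()[["pmid", "year", "citation_count"]].copy()
    df["percentile"] = np.nan
    for _, idx in df.groupby("year").groups.items():
        df.loc[idx, "percentile"] = cohort_percentiles(
            df.loc[idx, "citation_count"].to_numpy())
    cohort_sizes = df.groupby("year")["pmid"].transform("size")
    df["highly_cited"] = df["percentile"] >= HIGHLY_CITED_PERCENTILE
    df["low_cohort"] = cohort_sizes < LOW_COHORT_SIZE
    return df


def is_clinical_trial(publication_types: list[str]) -> bool:
    """True iff any publication-type string contains 'clinical trial',
    case-insensitively (substring match, by construction of the source
    labels)."""
    return any("clinical trial" in t.lower() for t in publication_types)


def clinical_citation_stats(graph: CitationGraph, pmid) -> tuple[bool, int | None]:
    """(cited by >=1 clinical trial, years until the first such citation).

    The lag is floored at 0; None when no trial ever cites the publication.
    """
    trial_years = [
        int(graph.nodes.at[citer, "year"])
        for citer in graph.citers(pmid)
        if is_clinical_trial(graph.nodes.at[citer, "publication_types"])
    ]
    if not trial_years:
        return False, None
    lag = max(0, min(trial_years) - int(graph.nodes.at[pmid, "year"]))
    return True, lag


@dataclass(frozen=True)
class DisruptionResult:
    pmid: object
    n_focal_only: int
    n_both: int
    n_ref_only: int

    @property
    def d_index(self) -> float | None:
        denom = self.n_focal_only + self.n_both + self.n_ref_only
        if denom == 0:
            return None
        return (self.n_focal_only - self.n_both) / denom


def disruption_index(graph: CitationGraph, pmid) -> DisruptionResult:
    """Classify every publication citing the focal paper or >=1 of its
    references.  Citations from the focal publication's own year count; the
    focal paper itself never counts as its own citer."""
    refs = graph.references(pmid)
    focal_citers = graph.citers(pmid) - {pmid}
    ref_citers = set()
    for r in refs:
        ref_citers |= graph.citers(r)
    ref_citers.discard(pmid)
    both = focal_citers & ref_citers
    return DisruptionResult(
        pmid=pmid,
        n_focal_only=len(focal_citers - ref_citers),
        n_both=len(both),
        n_ref_only=len(ref_citers - focal_citers),
    )


def disruption_table(graph: CitationGraph, pmids=None) -> pd.DataFrame:
    """Disruption index for each publication plus its within-year percentile
    of the index (publications with an undefined index are excluded from the
    cohorts)."""
    if pmids is None:
        pmids = list(graph.nodes.index)
    rows = []
    for p in pmids:
        r = disruption_index(graph, p)
        rows.append({"pmid": p, "n_focal_only": r.n_focal_only,
                     "n_both": r.n_both, "n_ref_only": r.n_ref_only,
                     "d_index": r.d_index if r.d_index is not None else np.nan})
    df = pd.DataFrame(rows)
    df["year"] = df["pmid"].map(graph.nodes["year"])
    df["percentile"] = np.nan
    defined = df["d_index"].notna()
    for _, idx in df[defined].groupby("year").groups.items():
        df.loc[idx, "percentile"] = cohort_percentiles(
            df.loc[idx, "d_index"].to_numpy())
    return df


def citation_variability(
    percentile_frame: pd.DataFrame,
    window: int = 3,
) -> pd.DataFrame:
    """IQR width (P75 - P25, linear-interpolation quartiles) of within-year
    citation percentiles per age class in a sliding window.

    ``percentile_frame`` needs columns year, age_class and percentile.  Cells
    with fewer than 4 members are reported NaN.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and positive, got {window}")
    half = window // 2
    years = percentile_frame["year"]
    rows = []
    for center in range(int(years.min()), int(years.max()) + 1):
        wf = percentile_frame[years.between(center - half, center + half)]
        for cls, cell in wf.groupby("age_class"):
            vals = cell["percentile"].dropna().to_numpy()
            if len(vals) < 4:
                width = np.nan
            else:
                q25, q75 = np.percentile(vals, [25, 75])
                width = q75 - q25
            rows.append({"center_year": center, "age_class": cls,
                         "iqr_width": width, "n": len(vals)})
    return pd.DataFrame(rows)
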