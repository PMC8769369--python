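"""Synthetic literature corpora with known ground truth.

The generator emits the five input tables the pipeline consumes
(publications, mentions, curated gene links, gene registry, citations) for a
corpus whose generating parameters are known, so that every downstream
statistic has a recoverable target:

* per-year publication counts with a decaying novelty rate (the probability
  that a publication introduces a never-highlighted gene) and
  rich-get-richer gene reuse (attachment weight ``(pair count + s)^alpha``),
* class-dependent team sizes and gene counts per publication,
* per-journal multipliers on the rate of recent-target publications; the
  default journal set is calibrated so the probability-weighted multiplier
  sum is 1, making each journal's planted corpus-denominator fold equal its
  multiplier exactly in expectation,
* phrase-labelled genome-biology / GWAS publications,
* a high-citation flag planted at 5% overall with class-dependent boosts
  (new : recent : old = 2 : 1.5 : 1), clinical-trial publication types, and a
  within-corpus reference/citation graph for the disruption index.

Text generation is skeletal — gene symbols embedded in filler tokens — and
offset consistency with the mention table is the contract, not linguistic
realism.  Gene symbols are synthetic (G000001...) and avoid lexicon phrases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["JournalSpec", "CorpusParams", "GroundTruth", "SyntheticCorpus",
           "generate_corpus", "make_toy_fixture"]

GB_PHRASE = "transcriptome"
GWAS_PHRASE = "genome-wide association study"
GWAS_MESH = "D055106:Genome-Wide Association Study"
FILLER_MESH = "D009369:Neoplasms"
FILLER_KEYWORD = "molecular biology"
TAXON = 9606


@dataclass(frozen=True)
class JournalSpec:
    name: str
    prob: float
    recent_multiplier: float = 1.0


#: probability-weighted multiplier sum is exactly 1.0, so planted folds are
#: the multipliers themselves
DEFAULT_JOURNALS = (
    JournalSpec("J Basic Res", 0.30, 0.2),
    JournalSpec("J Clin Stud", 0.20, 0.2),
    JournalSpec("Mol Biol Rep", 0.15, 1.0),
    JournalSpec("Cell Res Lett", 0.15, 1.0),
    JournalSpec("Genome Front", 0.10, 2.0),
    JournalSpec("Nov Gene Disc", 0.10, 4.0),
)

FUNDERS = (("NIH", 0.30), ("ERC", 0.12), ("HHMI", 0.05), ("WELLCOME", 0.10))
ACTIVITY_CODES = ("R01", "U01", "F32", "ZIA")
ORGANIZATIONS = ("Univ A", "Univ B", "Inst C", "Hosp D", "Center E")


@dataclass
class CorpusParams:
    """Generating conditions; the defaults describe the study conditions the
    recovery tests assume (about 5,000 publications, class mix 5/15/80 in the
    settled regime, journal multipliers {0.2, 1, 2, 4})."""

    n_genes: int = 1500
    year_start: int = 1980
    year_end: int = 2018
    pubs_per_year: int = 128
    #: asymptotic probability that a publication introduces a new gene
    novelty_base: float = 0.05
    #: initial novelty rate, decaying exponentially toward the base
    novelty_init: float = 0.60
    novelty_tau: float = 3.0
    #: probability (per unit journal multiplier) of a recent-class publication
    recent_rate: float = 0.15
    attachment_exponent: float = 1.0
    attachment_smoothing: float = 1.0
    #: mean number of extra (always old-class) genes per publication, by class
    extra_gene_mean: dict = field(default_factory=lambda: {
        "new": 2.0, "recent": 1.0, "old": 0.5})
    max_genes_per_pub: int = 12
    team_size_mean: dict = field(default_factory=lambda: {
        "new": 8.0, "recent": 6.0, "old": 4.0})
    journals: tuple = DEFAULT_JOURNALS
    genome_biology_fraction: float = 0.30
    gwas_phrase_fraction: float = 0.03
    gwas_mesh_fraction: float = 0.02
    gwas_catalog_fraction: float = 0.01
    review_fraction: float = 0.03
    trial_type_fraction: float = 0.05
    ambiguous_mention_fraction: float = 0.05
    noncoding_mention_fraction: float = 0.05
    #: relative probability of the planted high-citation flag, by class
    high_cite_relative_boost: dict = field(default_factory=lambda: {
        "new": 2.0, "recent": 1.5, "old": 1.0})
    high_cite_base_rate: float = 0.05
    reference_mean: float = 3.0
    seed: int = 0

    def novelty_rate(self, year: int) -> float:
        decay = np.exp(-(year - self.year_start) / self.novelty_tau)
        return self.novelty_base + (self.novelty_init - self.novelty_base) * decay

    @property
    def class_mix(self) -> dict:
        """Publication-class probabilities in the settled (late-year) regime."""
        new = self.novelty_base
        recent = self.recent_rate  # weighted multiplier sum is 1 by calibration
        return {"new": new, "recent": recent, "old": 1.0 - new - recent}

    def expected_pair_shares(self) -> dict:
        """Planted pair-level class mixture in the settled regime.

        Extra genes are always old, so new/recent pairs arise only as a
        publication's focal gene.
        """
        mix = self.class_mix
        mean_pairs = 1.0 + sum(mix[c] * self.extra_gene_mean[c] for c in mix)
        return {"new": mix["new"] / mean_pairs,
                "recent": mix["recent"] / mean_pairs,
                "old": (mix["old"] + sum(mix[c] * self.extra_gene_mean[c]
                                         for c in mix)) / mean_pairs}

    def high_cite_prob(self, cls: str) -> float:
        mix = self.class_mix
        rel = self.high_cite_relative_boost
        scale = self.high_cite_base_rate / sum(mix[c] * rel[c] for c in mix)
        return scale * rel[cls]

    def validate(self) -> None:
        probs = [j.prob for j in self.journals]
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("journal probabilities must sum to 1")
        if self.novelty_init > 1 or self.novelty_base < 0:
            raise ValueError("novelty rates must be probabilities")
        worst = self.novelty_base + self.recent_rate * max(
            j.recent_multiplier for j in self.journals)
        if worst >= 1.0:
            raise ValueError("novelty + maximal recent rate must stay below 1")
        n_pubs = self.pubs_per_year * (self.year_end - self.year_start + 1)
        expected_new = sum(self.novelty_rate(y) * self.pubs_per_year
                           for y in range(self.year_start, self.year_end + 1))
        if expected_new > 0.9 * self.n_genes:
            raise ValueError(
                f"novelty schedule demands ~{expected_new:.0f} new genes "
                f"but the pool holds only {self.n_genes}")
        if n_pubs <= 0:
            raise ValueError("empty year range")


@dataclass
class GroundTruth:
    """What the generator actually did, in recoverable form."""

    gene_first_year: pd.Series          # gene_id -> true discovery year
    publications: pd.DataFrame          # pmid, year, journal, true_class, gb, gwas, high_cite
    pairs: pd.DataFrame                 # the internal (pmid, gene_id) pair table
    journal_folds: pd.Series            # journal -> planted recent fold
    catalog_pmids: frozenset            # GWAS-catalog route members
    expected_pair_shares: dict


@dataclass
class SyntheticCorpus:
    publications: pd.DataFrame
    mentions: pd.DataFrame
    gene_links: pd.DataFrame
    registry: pd.DataFrame
    citations: pd.DataFrame
    citation_counts: pd.DataFrame
    ground_truth: GroundTruth
    params: CorpusParams

    def write(self, out_dir: str | Path) -> dict:
        """Serialise the five input tables (and ground truth) as TSVs."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pubs = self.publications.copy()
        for col in ("keywords", "mesh_terms", "publication_types", "funders",
                    "activity_codes", "organizations"):
            pubs[col] = pubs[col].map("|".join)
        paths = {}
        for name, frame in (
            ("publications", pubs),
            ("mentions", self.mentions),
            ("gene2pubmed", self.gene_links),
            ("gene_info", self.registry),
            ("citations", self.citations),
            ("citation_counts", self.citation_counts),
            ("truth_pubs", self.ground_truth.publications),
            ("truth_pairs", self.ground_truth.pairs),
        ):
            path = out / f"{name}.tsv"
            frame.to_csv(path, sep="\t", index=False)
            paths[name] = path
        return paths


def _sample_weighted(rng, candidates: np.ndarray, counts: np.ndarray,
                     exponent: float, smoothing: float, k: int = 1) -> np.ndarray:
    w = (counts + smoothing) ** exponent
    w = w / w.sum()
    k = min(k, len(candidates))
    return rng.choice(candidates, size=k, replace=False, p=w)


def _compose_text(pmid: int, symbols: list[str]) -> tuple[str, str, list]:
    """Title/abstract with each gene symbol at a recorded offset.

    Offsets index the concatenation title + one separator + abstract.
    """
    title_syms = symbols[:2]
    title = "Characterization of "
    mentions = []
    for i, s in enumerate(title_syms):
        if i:
            title += " and "
        mentions.append((pmid, len(title), s))
        title += s
    title += " in human samples."
    abstract = "We investigated "
    base = len(title) + 1
    for i, s in enumerate(symbols):
        if i:
            abstract += ", "
        mentions.append((pmid, base + len(abstract), s))
        abstract += s
    abstract += " with standard experiments and report findings."
    return title, abstract, mentions


def generate_corpus(params: CorpusParams | None = None) -> SyntheticCorpus:
    params = params or CorpusParams()
    params.validate()
    rng = np.random.default_rng(params.seed)

    gene_ids = np.array([str(100000 + i) for i in range(params.n_genes)])
    symbols = {g: f"G{i:06d}" for i, g in enumerate(gene_ids)}
    unused = list(gene_ids)
    rng.shuffle(unused)
    first_year: dict[str, int] = {}
    pair_count: dict[str, int] = {}
    # genes grouped by first-highlight year for fast recent/old pools
    by_year: dict[int, list[str]] = {}

    j_names = [j.name for j in params.journals]
    j_probs = np.array([j.prob for j in params.journals])
    j_mult = {j.name: j.recent_multiplier for j in params.journals}

    pub_rows, mention_rows, link_rows, pair_rows, truth_rows = [], [], [], [], []
    pmid = 100000

    def pool(year: int, cls: str) -> list[str]:
        if cls == "recent":
            lo, hi = year - 5, year - 1
        else:
            lo, hi = params.year_start - 100, year - 6
        out: list[str] = []
        for y in range(max(lo, params.year_start), hi + 1):
            out.extend(by_year.get(y, ()))
        return out

    for year in range(params.year_start, params.year_end + 1):
        novelty = params.novelty_rate(year)
        # pools are static within a year: genes first highlighted this year
        # only become recent/old candidates in later years
        recent_pool = pool(year, "recent")
        old_pool_year = pool(year, "old")
        for _ in range(params.pubs_per_year):
            pmid += 1
            journal = j_names[rng.choice(len(j_names), p=j_probs)]

            if rng.random() < params.review_fraction:
                # non-research decoy: filtered out downstream, mentions none
                pub_rows.append({
                    "pmid": pmid, "year": year, "journal": journal,
                    "title": "A review of the field.", "abstract": "",
                    "keywords": [FILLER_KEYWORD], "mesh_terms": [FILLER_MESH],
                    "publication_types": ["D016454:Review"],
                    "n_authors": 2, "funders": [], "activity_codes": [],
                    "organizations": []})
                continue

            r_recent = params.recent_rate * j_mult[journal]
            u = rng.random()
            if u < novelty:
                cls = "new"
            elif u < novelty + r_recent:
                cls = "recent"
            else:
                cls = "old"
            # feasibility fallbacks (only bite during the warm-up years)
            if cls == "recent" and not recent_pool:
                cls = "old" if old_pool_year else "new"
            if cls == "old" and not old_pool_year:
                cls = "recent" if recent_pool else "new"
            if cls == "new" and not unused:
                cls = "old" if old_pool_year else "recent"

            if cls == "new":
                focal = unused.pop()
                first_year[focal] = year
                by_year.setdefault(year, []).append(focal)
            else:
                cand = np.array(recent_pool if cls == "recent" else old_pool_year)
                counts = np.array([pair_count.get(g, 0) for g in cand], dtype=float)
                focal = str(_sample_weighted(
                    rng, cand, counts, params.attachment_exponent,
                    params.attachment_smoothing)[0])

            mean_extra = params.extra_gene_mean[cls]
            n_extra = int(min(rng.geometric(1.0 / (1.0 + mean_extra)) - 1,
                              params.max_genes_per_pub - 1))
            old_pool = [g for g in old_pool_year if g != focal]
            extras: list[str] = []
            if n_extra > 0 and old_pool:
                cand = np.array(old_pool)
                counts = np.array([pair_count.get(g, 0) for g in cand], dtype=float)
                extras = [str(g) for g in _sample_weighted(
                    rng, cand, counts, params.attachment_exponent,
                    params.attachment_smoothing, k=n_extra)]
            genes = [focal] + extras
            for g in genes:
                pair_count[g] = pair_count.get(g, 0) + 1

            title, abstract, ment = _compose_text(pmid, [symbols[g] for g in genes])
            sym_to_gene = {symbols[g]: g for g in genes}
            for (p, off, s) in ment:
                mention_rows.append({"pmid": p, "char_offset": off,
                                     "mention_text": s,
                                     "gene_id": sym_to_gene[s],
                                     "entity_type": "Gene"})
            abstract_start = len(title) + 1
            if rng.random() < params.ambiguous_mention_fraction:
                mention_rows.append({"pmid": pmid, "char_offset": abstract_start,
                                     "mention_text": "ambiguous",
                                     "gene_id": f"{gene_ids[0]};{gene_ids[1]}",
                                     "entity_type": "Gene"})
            if rng.random() < params.noncoding_mention_fraction:
                mention_rows.append({"pmid": pmid, "char_offset": abstract_start,
                                     "mention_text": "NC0001",
                                     "gene_id": "nc0001",
                                     "entity_type": "Gene"})

            keywords = [FILLER_KEYWORD]
            mesh = [FILLER_MESH]
            gb_phrase = rng.random() < params.genome_biology_fraction
            gwas_phrase = rng.random() < params.gwas_phrase_fraction
            gwas_mesh = rng.random() < params.gwas_mesh_fraction
            in_catalog = rng.random() < params.gwas_catalog_fraction
            if gb_phrase:
                keywords.append(GB_PHRASE)
            if gwas_phrase:
                keywords.append(GWAS_PHRASE)
            if gwas_mesh:
                mesh.append(GWAS_MESH)
            # the GWAS phrase and MeSH name both contain "genome-wide", a
            # genome-biology lexicon token, so they set the field label too
            truth_gb = gb_phrase or gwas_phrase or gwas_mesh
            truth_gwas = gwas_phrase or gwas_mesh or in_catalog

            pub_types = ["D016428:Journal Article"]
            if rng.random() < params.trial_type_fraction:
                pub_types.append("D016430:Clinical Trial")

            n_authors = 1 + int(rng.poisson(params.team_size_mean[cls] - 1.0))
            funders = [name for name, p in FUNDERS if rng.random() < p]
            codes = ([str(rng.choice(ACTIVITY_CODES))]
                     if "NIH" in funders and rng.random() < 0.8 else [])
            orgs = [str(rng.choice(ORGANIZATIONS))] if rng.random() < 0.5 else []

            high_cite = rng.random() < params.high_cite_prob(cls)

            pub_rows.append({
                "pmid": pmid, "year": year, "journal": journal,
                "title": title, "abstract": abstract, "keywords": keywords,
                "mesh_terms": mesh, "publication_types": pub_types,
                "n_authors": n_authors, "funders": funders,
                "activity_codes": codes, "organizations": orgs})
            for g in genes:
                link_rows.append({"tax_id": TAXON, "gene_id": g, "pmid": pmid})
                pair_rows.append({"pmid": pmid, "gene_id": g,
                                  "pub_year": year,
                                  "in_title": g in genes[:2],
                                  "in_abstract": True})
            truth_rows.append({"pmid": pmid, "year": year, "journal": journal,
                               "true_class": cls, "genome_biology": truth_gb,
                               "gwas": truth_gwas, "in_catalog": in_catalog,
                               "high_cite": high_cite,
                               "is_trial": "D016430:Clinical Trial" in pub_types})

    publications = pd.DataFrame(pub_rows)
    mentions = pd.DataFrame(mention_rows)
    gene_links = pd.DataFrame(link_rows)
    truth_pubs = pd.DataFrame(truth_rows)
    pairs = pd.DataFrame(pair_rows).sort_values(
        ["pmid", "gene_id"]).reset_index(drop=True)

    registry_rows = [{"gene_id": g, "symbol": symbols[g], "tax_id": TAXON,
                      "gene_type": "protein-coding",
                      "lof_intolerant": bool(rng.random() < 0.15),
                      "murine_phenotype_count": int(rng.poisson(2.0)),
                      "gwas_trait_count": int(rng.poisson(1.0))}
                     for g in gene_ids]
    registry_rows.append({"gene_id": "nc0001", "symbol": "NC0001",
                          "tax_id": TAXON, "gene_type": "ncRNA",
                          "lof_intolerant": False,
                          "murine_phenotype_count": 0, "gwas_trait_count": 0})
    registry_rows.append({"gene_id": "mm0001", "symbol": "Mm0001",
                          "tax_id": 10090, "gene_type": "protein-coding",
                          "lof_intolerant": False,
                          "murine_phenotype_count": 0, "gwas_trait_count": 0})
    registry = pd.DataFrame(registry_rows)

    # citation graph: each research publication cites earlier publications
    research = truth_pubs[["pmid", "year", "true_class", "high_cite"]]
    pmids_by_year: dict[int, np.ndarray] = {
        y: sub["pmid"].to_numpy() for y, sub in research.groupby("year")}
    years_sorted = sorted(pmids_by_year)
    earlier: dict[int, np.ndarray] = {}
    acc: list[np.ndarray] = []
    for y in years_sorted:
        earlier[y] = np.concatenate(acc) if acc else np.empty(0, dtype=int)
        acc.append(pmids_by_year[y])
    edge_rows = []
    for p, y in zip(research["pmid"], research["year"]):
        cand = earlier[y]
        if len(cand) == 0:
            continue
        k = min(int(rng.poisson(params.reference_mean)), len(cand))
        if k == 0:
            continue
        for cited in rng.choice(cand, size=k, replace=False):
            edge_rows.append({"citing_pmid": int(p), "cited_pmid": int(cited)})
    citations = pd.DataFrame(edge_rows, columns=["citing_pmid", "cited_pmid"])

    low = np.minimum(np.floor(rng.lognormal(1.0, 1.0, size=len(research))), 100)
    high = 150 + rng.poisson(30, size=len(research))
    counts = np.where(research["high_cite"].to_numpy(), high, low).astype(int)
    citation_counts = pd.DataFrame({"pmid": research["pmid"].to_numpy(),
                                    "citation_count": counts})

    truth = GroundTruth(
        gene_first_year=pd.Series(first_year, name="first_year"),
        publications=truth_pubs,
        pairs=pairs,
        journal_folds=pd.Series(j_mult, name="planted_fold"),
        catalog_pmids=frozenset(truth_pubs.loc[truth_pubs["in_catalog"], "pmid"]),
        expected_pair_shares=params.expected_pair_shares(),
    )
    return SyntheticCorpus(publications, mentions, gene_links, registry,
                           citations, citation_counts, truth, params)


def make_toy_fixture(name: str) -> dict:
    """Tiny hand-specified fixtures with hand-verifiable expected statistics."""
    if name == "fisher-worked":
        # journal J: 10 publications, 1 target; elsewhere: 14 publications,
        # 11 targets -> table (1, 9, 11, 3)
        pmids = list(range(1, 25))
        journals = ["J"] * 10 + ["K"] * 14
        targets = {1} | set(range(11, 22))
        records = pd.DataFrame({"pmid": pmids, "journal": journals})
        return {"records": records, "target_pmids": targets,
                "expected_table": (1, 9, 11, 3)}
    if name == "disruption-0.4":
        # citers of focal only: 3; of focal and a reference: 1; of a
        # reference only: 1 -> d = (3 - 1) / 5 = 0.4
        edges = pd.DataFrame(
            [("F", "R1"), ("F", "R2"),
             ("A", "F"), ("B", "F"), ("C", "F"),
             ("D", "F"), ("D", "R1"),
             ("E", "R2")],
            columns=["citing_pmid", "cited_pmid"])
        nodes = pd.DataFrame({
            "pmid": ["F", "R1", "R2", "A", "B", "C", "D", "E"],
            "year": [2000, 1995, 1996, 2002, 2003, 2003, 2004, 2005],
            "publication_types": [["D016428:Journal Article"]] * 8,
        })
        return {"edges": edges, "nodes": nodes, "focal": "F",
                "expected_d": 0.4}
    if name == "two-block-journals":
        genes = [f"g{i}" for i in range(6)]
        rows = {}
        for j in range(6):
            cells = [30.0 if (j < 3) == (i < 3) else 0.0 for i in range(6)]
            rows[f"journal{j}"] = cells
        matrix = pd.DataFrame(rows, index=genes).T
        matrix.columns = genes
        return {"matrix": matrix,
                "row_blocks": ({f"journal{j}" for j in range(3)},
                               {f"journal{j}" for j in range(3, 6)})}
    raise ValueError(f"unknown fixture {name!r}")
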