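"""Reading the input table dialects and building the gene-highlight table.

Four tabular inputs drive the pipeline:

* ``publications.tsv`` — one MEDLINE-derived record per row with bibliographic,
  funding and affiliation metadata (list-valued fields ``|``-delimited),
* ``mentions.tsv`` — PubTator-style gene mentions with character offsets into
  the concatenated title + abstract,
* ``gene2pubmed.tsv`` — curated gene-to-publication links (tax_id, gene_id, pmid),
* ``gene_info.tsv`` — the gene registry, optionally extended with annotation
  columns (loss-of-function intolerance, murine phenotype counts, GWAS trait
  counts).

The end product is the *highlight table*: unique (publication, gene) pairs in
which a human protein-coding gene is mentioned by name in the title or
abstract of a research publication.  Nearly every downstream statistic counts
these pairs.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "DEFAULT_EXCLUDED_TYPES",
    "DEFAULT_TAXON",
    "FormatError",
    "read_publications",
    "read_mentions",
    "read_gene_links",
    "read_gene_registry",
    "filter_research_publications",
    "locate_mention_section",
    "build_highlight_table",
    "false_negative_upper_bound",
]

#: MeSH publication types that disqualify a record as a research publication.
DEFAULT_EXCLUDED_TYPES = (
    "D016454:Review",
    "D016422:Letter",
    "D016420:Comment",
    "D016421:Editorial",
    "D016456:Historical Article",
    "D016433:News",
    "D019215:Biography",
    "D016425:Published Erratum",
    "D054711:Introductory Journal Article",
    "D019477:Portrait",
    "D017203:Interview",
    "D016424:Overall",
    "D017065:Practice Guideline",
    "D059040:Video-Audio Media",
    "D018431:Newspaper Article",
    "D016417:Bibliography",
    "D016440:Retraction of Publication",
    "D016441:Retracted Publication",
    "D019531:Lecture",
    "D016435:Directory",
    "D016419:Classical Article",
    "D019484:Address",
    "D029282:Patient Education Handout",
    "D062210:Personal Narrative",
    "D020493:Autobiography",
    "D020485:Legislation",
    "D016221:Festschrift",
    "D016438:Duplicate Publication",
    "D057405:Webcast",
    "D064886:Dataset",
    "D016437:Dictionary",
    "D000075742:Expression of Concern",
    "D016453:Periodical Index",
    "D054710:Interactive Tutorial",
    "D016426:Scientific Integrity Review",
    "D020470:Collected Works",
)

DEFAULT_TAXON = 9606
DEFAULT_YEAR_MAX = 2018
#: separator characters assumed between title and abstract in mention offsets
DEFAULT_SEPARATOR_LEN = 1

LIST_FIELDS = ("keywords", "mesh_terms", "publication_types", "funders",
               "activity_codes", "organizations")
PUBLICATION_COLUMNS = ("pmid", "year", "journal", "title", "abstract") + \
    LIST_FIELDS[:3] + ("n_authors",) + LIST_FIELDS[3:]


class FormatError(ValueError):
    """An input file does not conform to the documented dialect."""


def _split_list(value) -> list[str]:
    if pd.isna(value) or value == "":
        return []
    return [tok for tok in str(value).split("|") if tok != ""]


def read_publications(path: str | Path) -> pd.DataFrame:
    """Load publication records; list fields are split, missing text is ''.

    The loader does not filter: duplicated pmids are kept for the filter stage
    to remove.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     na_values=[], quoting=3)
    missing = [c for c in PUBLICATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"publications file missing column(s): {', '.join(missing)}")
    for col in ("year", "n_authors"):
        try:
            df[col] = df[col].astype(int)
        except ValueError:
            bad = df.loc[~df[col].str.fullmatch(r"-?\d+"), "pmid"].tolist()
            raise FormatError(f"unparseable {col} for pmid(s): {bad[:5]}") from None
    df["pmid"] = df["pmid"].astype(int)
    for col in LIST_FIELDS:
        df[col] = df[col].map(_split_list)
    return df.reset_index(drop=True)


def read_mentions(path: str | Path) -> pd.DataFrame:
    """Load PubTator-style mentions; rows whose entity type is not Gene are ignored."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, quoting=3)
    missing = [c for c in ("pmid", "char_offset", "gene_id", "entity_type")
               if c not in df.columns]
    if missing:
        raise FormatError(f"mentions file missing column(s): {', '.join(missing)}")
    df = df[df["entity_type"] == "Gene"].copy()
    df["pmid"] = df["pmid"].astype(int)
    df["char_offset"] = df["char_offset"].astype(int)
    return df.reset_index(drop=True)


def read_gene_links(path: str | Path) -> pd.DataFrame:
    """Load curated gene-to-publication links (gene2pubmed layout)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("tax_id", "gene_id", "pmid") if c not in df.columns]
    if missing:
        raise FormatError(f"gene links file missing column(s): {', '.join(missing)}")
    df["tax_id"] = df["tax_id"].astype(int)
    df["pmid"] = df["pmid"].astype(int)
    return df.reset_index(drop=True)


def read_gene_registry(path: str | Path) -> pd.DataFrame:
    """Load the gene registry; absent annotation columns default to 0 / False."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("gene_id", "symbol", "tax_id", "gene_type")
               if c not in df.columns]
    if missing:
        raise FormatError(f"gene registry missing column(s): {', '.join(missing)}")
    if df["gene_id"].duplicated().any():
        raise FormatError("gene registry contains duplicated gene_id")
    df["tax_id"] = df["tax_id"].astype(int)
    if "lof_intolerant" not in df.columns:
        df["lof_intolerant"] = False
    else:
        df["lof_intolerant"] = df["lof_intolerant"].isin(["True", "true", "1"])
    for col in ("murine_phenotype_count", "gwas_trait_count"):
        if col not in df.columns:
            df[col] = 0
        else:
            df[col] = df[col].replace("", "0").astype(int)
    return df.reset_index(drop=True)


def _type_codes(publication_types: list[str]) -> set[str]:
    return {t.split(":", 1)[0] for t in publication_types}


def filter_research_publications(
    records: pd.DataFrame,
    year_max: int = DEFAULT_YEAR_MAX,
    excluded_types: tuple[str, ...] = DEFAULT_EXCLUDED_TYPES,
) -> pd.DataFrame:
    """Restrict to research publications.

    Removes records carrying any excluded publication type (matched on the
    MeSH descriptor code), records published after ``year_max``, and *all*
    copies of any duplicated pmid.  Idempotent.
    """
    excluded_codes = {t.split(":", 1)[0] for t in excluded_types}
    keep_type = records["publication_types"].map(
        lambda types: not (_type_codes(types) & excluded_codes))
    keep_year = records["year"] <= year_max
    dup = records["pmid"].duplicated(keep=False)
    return records[keep_type & keep_year & ~dup].reset_index(drop=True)


def locate_mention_section(
    char_offset: int,
    title_len: int,
    abstract_len: int,
    sep_len: int = DEFAULT_SEPARATOR_LEN,
) -> str:
    """Resolve an offset into the concatenated title + separator + abstract.

    Offsets are 0-based.  Returns ``'title'``, ``'abstract'`` or ``'beyond'``;
    offsets landing on the separator resolve to ``'beyond'``.
    """
    if char_offset < 0:
        raise ValueError(f"negative mention offset: {char_offset}")
    if char_offset < title_len:
        return "title"
    start = title_len + sep_len
    if abstract_len > 0 and start <= char_offset < start + abstract_len:
        return "abstract"
    return "beyond"


def build_highlight_table(
    records: pd.DataFrame,
    mentions: pd.DataFrame,
    links: pd.DataFrame,
    registry: pd.DataFrame,
    taxon: int = DEFAULT_TAXON,
    sep_len: int = DEFAULT_SEPARATOR_LEN,
) -> pd.DataFrame:
    """Build the unique (publication, gene) highlight table.

    Keeps mentions whose publication carries at least one curated human-gene
    link, drops ambiguously mapped mentions (gene_id containing ';'), mentions
    falling beyond the abstract, and genes that are absent from the registry,
    not protein-coding, or of a different taxon.  Duplicate mentions of a gene
    within one publication collapse to a single pair carrying the union of the
    sections it was seen in.

    Returns a frame with columns pmid, gene_id, pub_year, in_title, in_abstract.
    """
    empty = pd.DataFrame(columns=["pmid", "gene_id", "pub_year", "in_title",
                                  "in_abstract"])
    if len(mentions) == 0 or len(records) == 0:
        return empty

    linked_pmids = set(links.loc[links["tax_id"] == taxon, "pmid"])
    eligible_genes = set(
        registry.loc[(registry["tax_id"] == taxon)
                     & (registry["gene_type"] == "protein-coding"), "gene_id"])

    m = mentions[mentions["pmid"].isin(linked_pmids)
                 & ~mentions["gene_id"].str.contains(";")
                 & mentions["gene_id"].isin(eligible_genes)]
    if len(m) == 0:
        return empty

    meta = records.set_index("pmid")
    m = m[m["pmid"].isin(meta.index)].copy()
    if len(m) == 0:
        return empty
    title_len = meta["title"].str.len()
    abstract_len = meta["abstract"].str.len()
    m["section"] = [
        locate_mention_section(off, title_len[p], abstract_len[p], sep_len)
        for off, p in zip(m["char_offset"], m["pmid"])
    ]
    m = m[m["section"] != "beyond"]
    if len(m) == 0:
        return empty

    grouped = (
        m.assign(in_title=m["section"] == "title",
                 in_abstract=m["section"] == "abstract")
        .groupby(["pmid", "gene_id"], as_index=False)
        .agg(in_title=("in_title", "any"), in_abstract=("in_abstract", "any"))
    )
    grouped["pub_year"] = grouped["pmid"].map(meta["year"]).astype(int)
    return grouped[["pmid", "gene_id", "pub_year", "in_title",
                    "in_abstract"]].sort_values(["pmid", "gene_id"]).reset_index(drop=True)


def false_negative_upper_bound(
    n_true_missed: int,
    n_reviewed: int,
    n_no_overlap: int,
    n_with_overlap: int,
) -> float:
    """Extrapolated upper bound on the share of publications whose highlighted
    genes the mention pipeline misses entirely.

    A manual review of ``n_reviewed`` publications that carry curated gene
    links but no detected mention finds ``n_true_missed`` genuine misses; the
    miss rate is extrapolated to the ``n_no_overlap`` such publications and
    expressed relative to the publications the pipeline did capture.  Returned
    as a percentage.
    """
    if n_reviewed <= 0:
        raise ValueError("n_reviewed must be positive")
    missed = n_true_missed / n_reviewed * n_no_overlap
    return 100.0 * missed / (n_with_overlap + missed)
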