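"""Field labels: genome biology and genome-wide association studies.

Publications are labelled from their text fields against packaged phrase
lexica.  A publication is *genome biology* when its title, abstract,
author-supplied keywords, or MeSH descriptor names contain a lexicon phrase
(case-insensitively).  A publication is a *GWAS* when it carries the MeSH
descriptor D055106, appears in a supplied association-catalog pmid set, or
matches the GWAS phrase lexicon in title, abstract or keywords (MeSH names
are not consulted for this lexicon).

Matching is token-bounded by default: a phrase matches only where it is
delimited by non-alphanumeric characters or string edges, so the listed token
"wes" does not fire inside "western".  A raw-substring mode is available for
sensitivity analysis.
"""

from __future__ import annotations

import re
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "load_lexicon",
    "match_lexicon",
    "is_genome_biology",
    "is_gwas",
    "label_corpus",
    "GWAS_MESH_CODE",
]

GWAS_MESH_CODE = "D055106"


def load_lexicon(name_or_path: str | Path) -> tuple[str, ...]:
    """Load a phrase lexicon: the packaged ``genome_biology`` / ``gwas`` lists,
    or a custom one-phrase-per-line UTF-8 file."""
    if name_or_path in ("genome_biology", "gwas"):
        text = (resources.files("genelit.resources")
                .joinpath(f"{name_or_path}.txt").read_text("utf-8"))
    else:
        text = Path(name_or_path).read_text("utf-8")
    phrases = [line.strip().lower() for line in text.splitlines() if line.strip()]
    seen: dict[str, None] = dict.fromkeys(phrases)
    return tuple(seen)


@lru_cache(maxsize=32)
def _compiled(phrases: tuple[str, ...], mode: str) -> re.Pattern | tuple[str, ...]:
    if mode == "substring":
        return phrases
    # longest-first alternation so longer phrases win over embedded tokens
    alternation = "|".join(re.escape(p) for p in
                           sorted(phrases, key=len, reverse=True))
    return re.compile(rf"(?<![a-z0-9])(?:{alternation})(?![a-z0-9])")


def match_lexicon(
    text_fields: Iterable[str],
    phrases: Sequence[str],
    mode: str = "token",
) -> bool:
    """True iff any phrase occurs in any field, case-insensitively.

    ``mode='token'`` (default) requires phrase boundaries to fall on
    non-alphanumeric characters or field edges; ``mode='substring'`` is raw
    containment.
    """
    if mode not in ("token", "substring"):
        raise ValueError(f"unknown matching mode {mode!r}")
    pattern = _compiled(tuple(phrases), mode)
    for field in text_fields:
        if not field:
            continue
        text = field.lower()
        if mode == "substring":
            if any(p in text for p in pattern):
                return True
        elif pattern.search(text):
            return True
    return False


def _mesh_names(mesh_terms: list[str]) -> list[str]:
    return [t.split(":", 1)[1] if ":" in t else t for t in mesh_terms]


def _mesh_codes(mesh_terms: list[str]) -> set[str]:
    return {t.split(":", 1)[0] for t in mesh_terms}


def is_genome_biology(record, lexicon: Sequence[str], mode: str = "token") -> bool:
    """Genome-biology label from title, abstract, keywords and MeSH names."""
    fields = [record["title"], record["abstract"], *record["keywords"],
              *_mesh_names(record["mesh_terms"])]
    return match_lexicon(fields, lexicon, mode=mode)


def is_gwas(
    record,
    catalog_pmids: frozenset | set = frozenset(),
    lexicon: Sequence[str] | None = None,
    mode: str = "token",
) -> bool:
    """GWAS label: MeSH D055106, catalog membership, or phrase match in
    title/abstract/keywords."""
    if GWAS_MESH_CODE in _mesh_codes(record["mesh_terms"]):
        return True
    if record["pmid"] in catalog_pmids:
        return True
    if lexicon is None:
        lexicon = load_lexicon("gwas")
    fields = [record["title"], record["abstract"], *record["keywords"]]
    return match_lexicon(fields, lexicon, mode=mode)


def label_corpus(
    records: pd.DataFrame,
    catalog_pmids: frozenset | set = frozenset(),
    mode: str = "token",
) -> pd.DataFrame:
    """One (pmid, genome_biology, gwas) label row per record.

    The two flags are independent; "gwas" appears in both lexica, so a GWAS
    keyword makes both true.
    """
    gb_lex = load_lexicon("genome_biology")
    gwas_lex = load_lexicon("gwas")
    rows = []
    for record in records.to_dict("records"):
        rows.append({
            "pmid": record["pmid"],
            "genome_biology": is_genome_biology(record, gb_lex, mode=mode),
            "gwas": is_gwas(record, catalog_pmids, gwas_lex, mode=mode),
        })
    return pd.DataFrame(rows, columns=["pmid", "genome_biology", "gwas"])
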