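"""Shared fixtures: synthetic corpora and the tables derived from them.

The session-scoped corpora are generated once; tests treat them as read-only.
"""

from __future__ import annotations

import pytest

from genelit import corpus_io, gene_age
from genelit.synthetic_corpus import CorpusParams, generate_corpus


@pytest.fixture(scope="session")
def small_params() -> CorpusParams:
    return CorpusParams(n_genes=400, year_start=1990, year_end=2010,
                        pubs_per_year=40, seed=7)


@pytest.fixture(scope="session")
def small_corpus(small_params):
    return generate_corpus(small_params)


@pytest.fixture(scope="session")
def full_corpus():
    """Default study conditions: ~5,000 publications over 1980-2018."""
    return generate_corpus(CorpusParams(seed=1))


def _derive(corpus):
    records = corpus_io.filter_research_publications(corpus.publications)
    pairs = corpus_io.build_highlight_table(
        records, corpus.mentions, corpus.gene_links, corpus.registry)
    age_table = gene_age.first_highlight_years(pairs)
    pairs = gene_age.assign_age_classes(pairs, age_table)
    return records, pairs, age_table


@pytest.fixture(scope="session")
def small_derived(small_corpus):
    return _derive(small_corpus)


@pytest.fixture(scope="session")
def full_derived(full_corpus):
    return _derive(full_corpus)
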