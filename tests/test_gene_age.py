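"""Gene ages, temporal share series and decade aggregations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from genelit import gene_age, stats_core
from genelit.gene_age import (
    age_class,
    assign_age_classes,
    category_enrichment_series,
    cumulative_highlight_curve,
    decade_aggregate,
    first_highlight_years,
    pair_share_series,
    publication_age_class,
)
from genelit.synthetic_corpus import CorpusParams, generate_corpus


@pytest.mark.parametrize("pub_year,first_year,expected", [
    (2010, 2010, "new"),
    (2011, 2010, "recent"),
    (2015, 2010, "recent"),
    (2016, 2010, "old"),
])
def test_age_class_thresholds(pub_year, first_year, expected):
    assert age_class(pub_year, first_year) == expected


def test_age_class_rejects_inconsistent_years():
    with pytest.raises(ValueError):
        age_class(2009, 2010)


class TestFirstHighlightYears:
    def test_minimum_over_pairs(self):
        pairs = pd.DataFrame({
            "pmid": [1, 2, 3], "gene_id": ["g", "g", "h"],
            "pub_year": [2003, 1995, 2000],
            "in_title": [False, False, False],
            "in_abstract": [True, True, True]})
        table = first_highlight_years(pairs)
        assert table.at["g", "first_year"] == 1995
        # abstract-only genes carry no title year
        assert np.isnan(table.at["g", "first_year_title"])

    def test_title_year_never_precedes_first_year(self, small_derived):
        _, _, age_table = small_derived
        both = age_table.dropna()
        assert (both["first_year_title"] >= both["first_year"]).all()

    def test_exact_recovery_of_generator_discovery_years(self, small_corpus,
                                                         small_derived):
        _, _, age_table = small_derived
        truth = small_corpus.ground_truth.gene_first_year
        recovered = age_table["first_year"].astype(int).sort_index()
        pd.testing.assert_series_equal(
            recovered, truth.sort_index().astype(int),
            check_names=False, check_index_type=False)


class TestCumulativeCurve:
    def test_hand_counted_share(self):
        age_table = pd.DataFrame(
            {"first_year": [2000, 2001, 2001, 2005],
             "first_year_title": [2000, np.nan, 2002, np.nan]},
            index=["a", "b", "c", "d"])
        registry = pd.DataFrame({
            "gene_id": list("abcdefghij"), "symbol": list("abcdefghij"),
            "tax_id": [9606] * 10, "gene_type": ["protein-coding"] * 10})
        curve = cumulative_highlight_curve(age_table, registry, [2001, 2005])
        assert curve.set_index("year").at[2001, "share_highlighted"] == 0.3
        assert curve.set_index("year").at[2005, "share_highlighted"] == 0.4

    def test_monotone_nondecreasing(self, small_corpus, small_derived):
        _, _, age_table = small_derived
        curve = cumulative_highlight_curve(age_table, small_corpus.registry,
                                           range(1990, 2011))
        assert (curve["share_highlighted"].diff().dropna() >= 0).all()
        assert (curve["share_title"].diff().dropna() >= 0).all()
        assert curve["share_highlighted"].between(0, 1).all()

    def test_curve_constant_after_novelty_shutoff(self):
        params = CorpusParams(n_genes=300, year_start=1990, year_end=2010,
                              pubs_per_year=30, novelty_init=0.6,
                              novelty_base=0.0, novelty_tau=1.5, seed=3)
        corpus = generate_corpus(params)
        truth = corpus.ground_truth.gene_first_year
        # novelty decays to zero: no discoveries in the final years
        assert truth.max() < 2008

    def test_empty_registry_raises(self, small_derived):
        _, _, age_table = small_derived
        registry = pd.DataFrame(columns=["gene_id", "symbol", "tax_id",
                                         "gene_type"])
        with pytest.raises(ValueError):
            cumulative_highlight_curve(age_table, registry, [2000])


class TestPairShareSeries:
    def test_shares_sum_to_one_in_every_window(self, small_derived):
        _, pairs, _ = small_derived
        series = pair_share_series(pairs, n_boot=50, seed=0)
        sums = series.groupby("center_year")["share"].sum()
        assert sums.to_numpy() == pytest.approx(np.ones(len(sums)), abs=1e-9)

    def test_even_window_rejected(self, small_derived):
        _, pairs, _ = small_derived
        with pytest.raises(ValueError):
            pair_share_series(pairs, window=2)

    def test_single_class_window(self):
        pairs = pd.DataFrame({
            "pmid": [1, 2], "gene_id": ["g", "h"], "pub_year": [2010, 2010],
            "in_title": [True, True], "in_abstract": [True, True],
            "age_class": ["old", "old"], "age": [8, 9],
            "first_year": [2002, 2001]})
        series = pair_share_series(pairs, n_boot=20, seed=0)
        by_class = series.set_index("age_class")["share"]
        assert by_class["old"] == 1.0 and by_class["new"] == 0.0


class TestEnrichmentSeries:
    def test_observed_double_expected_gives_plus_one(self):
        # two genes discovered long ago, one recent; pairs concentrate 2:1 on
        # the recent one although gene counts are 1 recent vs 2 old
        pairs = pd.DataFrame({
            "pmid": [1, 2, 3, 4, 5, 6],
            "gene_id": ["r", "r", "r", "r", "o1", "o2"],
            "pub_year": [2010] * 6,
            "in_title": [True] * 6, "in_abstract": [True] * 6})
        age_table = pd.DataFrame({"first_year": [2008, 1990, 1990],
                                  "first_year_title": [2008, 1990, 1990]},
                                 index=["r", "o1", "o2"])
        with_cls = assign_age_classes(pairs, age_table)
        series = category_enrichment_series(with_cls, age_table, window=1,
                                            n_boot=20, seed=0)
        row = series[(series["center_year"] == 2010)
                     & (series["age_class"] == "recent")].iloc[0]
        # observed share 4/6 = 2/3; expected 1/3 of genes are recent
        assert row["enrichment"] == pytest.approx(1.0)
        old = series[(series["center_year"] == 2010)
                     & (series["age_class"] == "old")].iloc[0]
        assert old["enrichment"] == pytest.approx(np.log2((2 / 6) / (2 / 3)))

    def test_invariant_under_uniform_weight_rescaling(self, small_derived):
        _, pairs, age_table = small_derived
        base = category_enrichment_series(pairs, age_table, n_boot=10, seed=0)
        w = pd.Series(7.0, index=age_table.index)
        scaled = category_enrichment_series(pairs, age_table, weights=w,
                                            n_boot=10, seed=0)
        pd.testing.assert_frame_equal(base, scaled)

    def test_all_zero_weights_rejected(self, small_derived):
        _, pairs, age_table = small_derived
        w = pd.Series(0.0, index=age_table.index)
        with pytest.raises(ValueError):
            category_enrichment_series(pairs, age_table, weights=w,
                                       n_boot=10, seed=0)

    def test_zero_observed_share_yields_minus_inf_sentinel(self):
        pairs = pd.DataFrame({
            "pmid": [1], "gene_id": ["o"], "pub_year": [2010],
            "in_title": [True], "in_abstract": [True]})
        age_table = pd.DataFrame({"first_year": [1990, 2008],
                                  "first_year_title": [1990, 2008]},
                                 index=["o", "r"])
        with_cls = assign_age_classes(pairs, age_table)
        series = category_enrichment_series(with_cls, age_table, window=1,
                                            n_boot=10, seed=0)
        recent = series[series["age_class"] == "recent"].iloc[0]
        assert recent["enrichment"] == -np.inf


class TestPublicationClassAndDecades:
    def test_youngest_class_precedence(self):
        pairs = pd.DataFrame({
            "pmid": [1, 1, 1, 1, 2],
            "gene_id": list("abcde"),
            "age_class": ["new", "old", "old", "old", "recent"]})
        cls = publication_age_class(pairs)
        assert cls[1] == "new" and cls[2] == "recent"

    def test_hand_counted_cell(self):
        records = pd.DataFrame({
            "pmid": [1, 2], "year": [1995, 1995], "n_authors": [2, 4],
            "journal": ["J", "J"]})
        pairs = pd.DataFrame({
            "pmid": [1, 2], "gene_id": ["a", "b"], "pub_year": [1995, 1995],
            "age_class": ["new", "new"], "age": [0, 0],
            "in_title": [True, True], "in_abstract": [True, True]})
        for metric, expected in (("mean_authors", 3.0), ("median_authors", 3.0)):
            out = decade_aggregate(records, pairs, metric=metric,
                                   decades=((1990, 1999),), n_boot=20, seed=0)
            cell = out[out["age_class"] == "new"].iloc[0]
            assert cell["value"] == pytest.approx(expected)
        empty = out[out["age_class"] == "old"].iloc[0]
        assert np.isnan(empty["value"]) and empty["n"] == 0

    def test_team_size_ratio_recovery(self, full_corpus, full_derived):
        # the generator's new-class team-size mean is double the old-class mean
        records, pairs, _ = full_derived
        out = decade_aggregate(records, pairs, metric="mean_authors",
                               decades=((2000, 2018),), n_boot=200, seed=5)
        by_class = out.set_index("age_class")["value"]
        ratio = by_class["new"] / by_class["old"]
        assert 1.7 < ratio < 2.3

    def test_genes_per_publication_higher_for_new(self, full_derived):
        records, pairs, _ = full_derived
        out = decade_aggregate(records, pairs, metric="mean_genes",
                               decades=((2000, 2018),), n_boot=100, seed=5)
        by_class = out.set_index("age_class")["value"]
        assert by_class["new"] > by_class["old"]


def test_reuse_correlates_across_periods(full_derived):
    """Rich-get-richer reuse: per-gene publication counts correlate across
    disjoint periods (qualitative echo of the observed strong rank
    correlation)."""
    _, pairs, _ = full_derived
    early = pairs[pairs["pub_year"].between(1995, 2005)]
    late = pairs[pairs["pub_year"].between(2006, 2018)]
    counts = pd.DataFrame({
        "early": early.groupby("gene_id").size(),
        "late": late.groupby("gene_id").size()}).fillna(0)
    counts = counts[(counts["early"] + counts["late"]) > 0]
    rho = stats_core.spearman(counts["early"], counts["late"])
    assert rho > 0.3
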