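"""Concentration of recent-target research: ranking, top sets, clustering."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from genelit import concentration, context_enrich
from genelit.concentration import (
    ablation_retest,
    build_journal_gene_matrix,
    journal_topk_share,
    rank_recent_targets,
    top_set,
    top_set_size,
    ward_cluster,
)
from genelit.synthetic_corpus import make_toy_fixture


def _pairs(rows):
    return pd.DataFrame(rows, columns=["pmid", "gene_id", "pub_year",
                                       "age_class"])


def _age_table(first_years: dict):
    return pd.DataFrame({"first_year": pd.Series(first_years)})


class TestRanking:
    def test_tie_break_by_gene_id(self):
        pairs = _pairs([(i, g, 2012, "recent")
                        for i, g in enumerate(["g1"] * 5 + ["g2"] * 3 + ["g3"] * 3)])
        ages = _age_table({"g1": 2010, "g2": 2010, "g3": 2010})
        table = rank_recent_targets(pairs, ages, (2010, 2018))
        assert table["gene_id"].tolist() == ["g1", "g2", "g3"]
        assert table["rank"].tolist() == [0, 1, 2]

    def test_cumulative_share_reaches_one(self, full_derived):
        _, pairs, ages = full_derived
        table = rank_recent_targets(pairs, ages, (2010, 2018))
        assert table["cum_share"].iloc[-1] == pytest.approx(1.0)
        assert (table["cum_share"].diff().dropna() >= 0).all()

    def test_eligibility_window_allows_shifting_recency(self):
        # first highlighted 5 years before the period start: recent only in
        # the first period year, still eligible
        ages = _age_table({"g_edge": 2005, "g_out": 2004, "g_late": 2017})
        pairs = _pairs([(1, "g_edge", 2010, "recent")])
        table = rank_recent_targets(pairs, ages, (2010, 2018))
        assert set(table["gene_id"]) == {"g_edge", "g_late"}

    def test_zero_count_eligible_genes_kept(self):
        ages = _age_table({"g1": 2011, "g2": 2012})
        pairs = _pairs([(1, "g1", 2012, "recent")])
        table = rank_recent_targets(pairs, ages, (2010, 2018))
        assert table.set_index("gene_id").at["g2", "n_recent_pairs"] == 0

    def test_brute_force_tally_on_synthetic(self, full_derived):
        _, pairs, ages = full_derived
        period = (2010, 2018)
        table = rank_recent_targets(pairs, ages, period)
        brute = pairs[(pairs["pub_year"].between(*period))
                      & (pairs["age_class"] == "recent")]
        brute_counts = brute.groupby("gene_id").size()
        joined = table.set_index("gene_id")["n_recent_pairs"]
        for g, n in brute_counts.items():
            assert joined[g] == n
        assert joined.sum() == len(brute)

    def test_empty_period_rejected(self, full_derived):
        _, pairs, ages = full_derived
        with pytest.raises(ValueError):
            rank_recent_targets(pairs, ages, (2018, 2010))


class TestTopSet:
    def test_ceil_rule(self):
        assert top_set_size(100, 0.01) == 1
        assert top_set_size(3943, 0.01) == 40

    def test_uniform_counts_share_close_to_fraction(self):
        ages = _age_table({f"g{i:03d}": 2010 for i in range(100)})
        pairs = _pairs([(i, f"g{i:03d}", 2012, "recent") for i in range(100)])
        table = rank_recent_targets(pairs, ages, (2010, 2018))
        genes, share = top_set(table, 0.01)
        assert len(genes) == 1
        assert share == pytest.approx(0.01)

    def test_share_monotone_in_fraction(self, full_derived):
        _, pairs, ages = full_derived
        table = rank_recent_targets(pairs, ages, (2010, 2018))
        shares = [top_set(table, f)[1] for f in (0.01, 0.05, 0.2)]
        assert shares[0] <= shares[1] <= shares[2]


class TestJournalShares:
    def _setup(self):
        records = pd.DataFrame({
            "pmid": [1, 2, 3, 4], "year": [2012] * 4,
            "journal": ["A", "A", "A", "A"]})
        pairs = _pairs([(1, "top", 2012, "recent"), (2, "top", 2012, "recent"),
                        (3, "x", 2012, "recent"), (4, "y", 2012, "recent")])
        return records, pairs

    def test_half_on_top_genes(self):
        records, pairs = self._setup()
        out = journal_topk_share(pairs, records, ["A"], ["top"], (2010, 2018))
        assert out["A"] == pytest.approx(50.0)

    def test_all_recent_pairs_on_top_gene_gives_hundred(self):
        records, pairs = self._setup()
        out = journal_topk_share(pairs, records, ["A"], ["top", "x", "y"],
                                 (2010, 2018))
        assert out["A"] == pytest.approx(100.0)

    def test_journal_without_recent_pairs_absent(self):
        records, pairs = self._setup()
        out = journal_topk_share(pairs, records, ["B"], ["top"], (2010, 2018))
        assert "B" not in out.index


class TestJournalGeneMatrix:
    def test_cell_percentages(self):
        records = pd.DataFrame({
            "pmid": range(1, 11), "year": [2012] * 10, "journal": ["A"] * 10})
        pairs = _pairs([(p, "g", 2012, "recent") for p in (1, 2, 3, 4)])
        m = build_journal_gene_matrix(pairs, records, ["A"], ["g", "h"],
                                      (2010, 2018))
        assert m.at["A", "g"] == pytest.approx(40.0)
        assert m.at["A", "h"] == 0.0

    def test_rows_can_exceed_hundred(self):
        records = pd.DataFrame({"pmid": [1], "year": [2012], "journal": ["A"]})
        pairs = _pairs([(1, "g", 2012, "recent"), (1, "h", 2012, "recent")])
        m = build_journal_gene_matrix(pairs, records, ["A"], ["g", "h"],
                                      (2010, 2018))
        assert m.loc["A"].sum() == pytest.approx(200.0)

    def test_journal_without_period_publications_omitted(self):
        records = pd.DataFrame({"pmid": [1], "year": [2005], "journal": ["A"]})
        m = build_journal_gene_matrix(_pairs([]), records, ["A"], ["g"],
                                      (2010, 2018))
        assert "A" not in m.index


class TestWardClustering:
    def test_identical_rows_merge_first(self):
        matrix = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]],
                              index=["a", "b", "c"], columns=["g1", "g2"])
        out = ward_cluster(matrix)
        first_merge = out["row_linkage"][0, :2].astype(int)
        assert set(first_merge) == {0, 1}

    def test_planted_two_block_partition_recovered(self):
        from scipy.cluster.hierarchy import fcluster
        fx = make_toy_fixture("two-block-journals")
        out = ward_cluster(fx["matrix"])
        labels = fcluster(out["row_linkage"], t=2, criterion="maxclust")
        blocks = [set(np.array(out["row_labels"])[labels == k])
                  for k in (1, 2)]
        assert set(map(frozenset, blocks)) == set(
            map(frozenset, fx["row_blocks"]))

    def test_row_permutation_preserves_merge_heights(self):
        fx = make_toy_fixture("two-block-journals")
        base = ward_cluster(fx["matrix"])
        perm = fx["matrix"].iloc[::-1]
        permuted = ward_cluster(perm)
        assert np.allclose(sorted(base["row_linkage"][:, 2]),
                           sorted(permuted["row_linkage"][:, 2]))

    def test_degenerate_input_identity_order(self):
        matrix = pd.DataFrame([[1.0, 2.0]], index=["only"], columns=["a", "b"])
        out = ward_cluster(matrix)
        assert out["row_order"] == ["only"]
        assert out["row_linkage"] is None

    def test_newick_export_contains_labels(self):
        fx = make_toy_fixture("two-block-journals")
        out = ward_cluster(fx["matrix"])
        assert out["row_newick"].endswith(";")
        for label in fx["matrix"].index:
            assert label in out["row_newick"]


class TestAblation:
    def _corpus(self):
        # journal J's recent enrichment is carried entirely by one planted
        # gene; journal K has broad recent coverage
        rows, pmid = [], 0
        records_rows = []
        for _ in range(20):
            pmid += 1
            records_rows.append({"pmid": pmid, "year": 2012, "journal": "J"})
            rows.append((pmid, "planted", 2012, "recent"))
        for i in range(20):
            pmid += 1
            records_rows.append({"pmid": pmid, "year": 2012, "journal": "K"})
            rows.append((pmid, f"k{i}", 2012, "recent"))
        for _ in range(160):
            pmid += 1
            records_rows.append({"pmid": pmid, "year": 2012, "journal": "L"})
            rows.append((pmid, "oldgene", 2012, "old"))
        return pd.DataFrame(records_rows), _pairs(rows)

    def test_planted_gene_carries_enrichment(self):
        records, pairs = self._corpus()
        membership = context_enrich.membership_from_records(
            records.assign(journal=records["journal"]), "journal")
        period = (2010, 2018)
        surviving = ablation_retest(pairs, records, membership, ["planted"],
                                    period)
        assert "J" not in set(surviving["group"])
        assert "K" in set(surviving["group"])

    def test_empty_top_set_is_noop(self):
        records, pairs = self._corpus()
        membership = context_enrich.membership_from_records(records, "journal")
        period = (2010, 2018)
        corpus = set(records["pmid"])
        targets = context_enrich.target_publications(pairs, "recent")
        original = context_enrich.enrichment_scan(corpus, targets, membership)
        original = original[original["direction"] == "enriched"]
        ablated = ablation_retest(pairs, records, membership, [], period)
        assert set(ablated["group"]) == set(original["group"])

    def test_ablating_everything_empties_scan(self):
        records, pairs = self._corpus()
        membership = context_enrich.membership_from_records(records, "journal")
        ablated = ablation_retest(pairs, records, membership,
                                  pairs["gene_id"].unique().tolist(),
                                  (2010, 2018))
        assert len(ablated) == 0
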