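"""Enrichment scans over journals, funders, activity codes and organizations.

For each group (e.g. a journal) and a target class (publications highlighting
at least one *new*, or at least one *recent*, gene target) a 2x2 table is
formed — target/non-target publications inside versus outside the group — and
tested with the two-sided Fisher exact test.  Bonferroni control is applied
per scan, over the groups actually tested.  Fold enrichment is the group's
target share over the corpus-wide target share (log2); a group with no target
publications at all gets a -inf sentinel.

The new-versus-recent comparison flags groups whose *recent* fold (linear
ratio scale) is at least twice their *new* fold — groups disproportionately
attached to gene targets in the years just after their first highlight.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .stats_core import ContingencyTable, bonferroni_reject, fisher_exact_two_sided

__all__ = [
    "membership_from_records",
    "target_publications",
    "group_contingency",
    "log2_fold_enrichment",
    "enrichment_scan",
    "new_vs_recent_comparison",
]

GROUP_KINDS = {"journal": "journal", "funder": "funders",
               "activity_code": "activity_codes", "organization": "organizations"}


def membership_from_records(records: pd.DataFrame, group_kind: str) -> pd.DataFrame:
    """Long-format (pmid, group) membership for one group kind.

    Journals are single-valued; funders, activity codes and organizations are
    list-valued, so one publication may belong to several groups.
    """
    if group_kind not in GROUP_KINDS:
        raise ValueError(f"unknown group kind {group_kind!r}")
    col = GROUP_KINDS[group_kind]
    if group_kind == "journal":
        out = records[["pmid", col]].rename(columns={col: "group"})
        return out[out["group"] != ""].reset_index(drop=True)
    exploded = records[["pmid", col]].explode(col).dropna()
    exploded = exploded.rename(columns={col: "group"})
    return exploded.drop_duplicates().reset_index(drop=True)


def target_publications(pairs_with_class: pd.DataFrame, target_class: str) -> set:
    """Publications highlighting >=1 gene of the target class.

    ``new`` means gene age exactly 0; ``recent`` means age 1-5.
    """
    if target_class not in ("new", "recent"):
        raise ValueError(f"target_class must be 'new' or 'recent', got {target_class!r}")
    hit = pairs_with_class["age_class"] == target_class
    return set(pairs_with_class.loc[hit, "pmid"])


def group_contingency(
    corpus_pmids: set,
    target_pmids: set,
    member_pmids: set,
) -> ContingencyTable:
    """2x2 counts for one group within the corpus; publications counted once."""
    members = member_pmids & corpus_pmids
    targets = target_pmids & corpus_pmids
    a = len(members & targets)
    b = len(members) - a
    c = len(targets) - a
    d = len(corpus_pmids) - a - b - c
    return ContingencyTable(a, b, c, d)


def log2_fold_enrichment(t: ContingencyTable) -> float:
    """log2 of (group target share / corpus target share); -inf when the group
    has no target publications."""
    if t.a + t.b == 0:
        raise ValueError("empty group: a + b = 0")
    corpus_share = (t.a + t.c) / t.total
    if corpus_share == 0:
        raise ValueError("corpus target share is zero")
    if t.a == 0:
        return -np.inf
    return float(np.log2((t.a / (t.a + t.b)) / corpus_share))


def enrichment_scan(
    pub_pmids: Sequence | set,
    target_pmids: set,
    membership: pd.DataFrame,
    alpha: float = 0.01,
    min_group_size: int = 1,
) -> pd.DataFrame:
    """Fisher/Bonferroni scan of every group against the corpus.

    ``pub_pmids`` is the publication corpus of the period under study (the
    caller restricts to the period and to publications highlighting >=1
    gene); groups with fewer than ``min_group_size`` member publications are
    skipped before the Bonferroni correction, so m equals the number of
    groups actually tested.  Degenerate tables (no targets at all, or only
    targets) get p = 1.0, as the test carries no information there.
    """
    corpus = set(pub_pmids)
    targets = set(target_pmids) & corpus
    rows = []
    for group, sub in membership.groupby("group"):
        members = set(sub["pmid"]) & corpus
        if len(members) < min_group_size or len(members) == 0:
            continue
        t = group_contingency(corpus, targets, members)
        try:
            p = fisher_exact_two_sided(t)
        except ValueError:
            p = 1.0
        fold = log2_fold_enrichment(t) if (t.a + t.c) > 0 else np.nan
        rows.append({"group": group, "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                     "log2_fold": fold, "p_raw": p})
    result = pd.DataFrame(rows, columns=["group", "a", "b", "c", "d",
                                         "log2_fold", "p_raw"])
    if len(result) == 0:
        result["significant"] = pd.Series(dtype=bool)
        result["direction"] = pd.Series(dtype=object)
        return result
    result["significant"] = bonferroni_reject(result["p_raw"].tolist(), alpha)
    result["direction"] = "none"
    sig = result["significant"]
    result.loc[sig & (result["log2_fold"] > 0), "direction"] = "enriched"
    result.loc[sig & (result["log2_fold"] < 0), "direction"] = "depleted"
    return result.sort_values("group").reset_index(drop=True)


def new_vs_recent_comparison(
    results_new: pd.DataFrame,
    results_recent: pd.DataFrame,
) -> pd.DataFrame:
    """Per-group linear fold ratios for the two target classes, plus the
    disproportionate-recent flag (recent fold >= 2 x new fold, on the linear
    ratio scale; a -inf new fold with a finite recent fold flags true).

    Groups present in only one scan are reported with the missing side NaN
    and a missing flag.
    """
    merged = results_new[["group", "log2_fold"]].rename(
        columns={"log2_fold": "log2_fold_new"}).merge(
        results_recent[["group", "log2_fold"]].rename(
            columns={"log2_fold": "log2_fold_recent"}),
        on="group", how="outer")
    # -inf log2 fold maps to a linear ratio of exactly 0
    merged["fold_new"] = np.exp2(merged["log2_fold_new"])
    merged["fold_recent"] = np.exp2(merged["log2_fold_recent"])
    both = merged["fold_new"].notna() & merged["fold_recent"].notna()
    flag = pd.Series(pd.NA, index=merged.index, dtype="boolean")
    flag[both] = merged.loc[both, "fold_recent"] >= 2.0 * merged.loc[both, "fold_new"]
    merged["disproportionate_recent"] = flag
    return merged[["group", "fold_new", "fold_recent",
                   "disproportionate_recent"]].sort_values("group").reset_index(drop=True)
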