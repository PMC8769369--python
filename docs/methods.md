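# Methods

## The highlight table

The pipeline's unit of analysis is the unique (publication, gene) pair in
which a human protein-coding gene is mentioned by name in the title or
abstract of a research publication. Construction proceeds in three steps.

**Research filter.** Publication records are dropped when they carry any of
36 disqualifying MeSH publication types (reviews, letters, comments,
editorials, errata, …; matched on the descriptor code, so `D016454:Review`
and a bare `D016454` behave identically), when they post-date the analysis
end year (default 2018), or when their identifier is duplicated — in the
duplicated case *every* copy is removed rather than deduplicating to one.
The filter is idempotent and monotone in the excluded-type list.

**Mention resolution.** Gene mentions arrive as character offsets into the
concatenation of title and abstract. The offset convention is 0-based with a
configurable separator width between the two sections (default 1 character);
a mention resolves to `title` when its offset precedes the title's end, to
`abstract` when it falls inside the abstract span, and to `beyond` otherwise
(`beyond` mentions — e.g. into full text — are discarded). Since upstream
annotation dialects differ in their separator convention, the width is a
parameter and the generator/reader round-trip test pins the default.

**Intersection and collapse.** A mention survives when its publication
carries at least one curated human-gene link (the curation is applied at the
*publication* level; the mention's gene need not itself be curated for that
publication), its gene identifier is unambiguous (no `;`), and the gene is
present in the registry, protein-coding, and of the configured taxon
(default 9606). Surviving mentions collapse to unique pairs carrying the
union of the sections they were seen in.

A small utility extrapolates a manually reviewed miss rate among
publications with curated links but no detected mention to an upper bound on
the pipeline-level false-negative percentage.

## Gene ages and temporal series

A gene's first-highlight year is the minimum publication year over its
pairs; its age at a pair is the year difference, classed as **new** (0),
**recent** (1–5) or **old** (≥6). A publication takes the youngest class
among its genes (precedence new > recent > old), so early-stage research is
"≥1 new or recent gene target".

*Cumulative curves* report the share of registry protein-coding genes ever
highlighted (and ever title-mentioned) by each year, optionally restricted
to a gene subset such as loss-of-function-intolerant genes (pLI > 0.9 flags
in the registry).

*Pair-share series* pool pairs in a 3-year sliding window (the window must
be odd; the center year labels it) and report per-class shares, which sum to
1 by construction. Confidence intervals are percentile bootstrap over
publications: the resampling unit is the publication, carrying its vector of
per-class pair counts.

*Enrichment series* compare the observed pair share of a class with its
gene-count expectation: each gene contributes, in each calendar year of the
window, to the class it occupies that year; the per-year (optionally
weighted) class shares are averaged over the window. Enrichment is
log₂(observed/expected). Weighting by registry annotations (murine phenotype
counts, GWAS trait counts) replaces the per-gene unit weight; enrichment is
invariant under uniform weight rescaling. Sentinels: observed 0 with
positive expectation reports −∞ (excluded from CI aggregation); zero
expectation leaves the cell undefined (NaN). Whether the expectation should
use per-year or window-pooled gene tallies is genuinely underdetermined; the
per-year-averaged construction was chosen for symmetry with the pooling of
pairs and is the only one implemented.

*Decade aggregates* report mean/median team size and highlighted-gene counts
per (decade × publication class) with bootstrap CIs over publications; the
decades are 1970–79 … 2000–09 and a final 2010–2018 period truncated at the
analysis end year. Empty cells are reported as not applicable (NaN).

## Statistical primitives

All stages share one implementation of each primitive (`stats_core`):

* **Fisher exact, two-sided** by the probability-mass rule: the p-value sums
  hypergeometric probabilities of all tables with the observed margins whose
  probability is at most that of the observed table. A relative slack of
  1e-7 on the ≤ comparison absorbs floating-point noise in the mass; the
  test suite checks agreement with exact Fraction-arithmetic enumeration to
  1e-12 relative error on every table with total ≤ 60. Zero margins raise.
* **Bonferroni** with inclusive threshold p ≤ α/m, m = tests per scan;
  default α = 0.01.
* **Percentile bootstrap** (not BCa), default 1,000 replicates, resampling
  unit = the rows passed in (publications for publication-level statistics,
  pairs where the statistic is pair-based); deterministic given a seed.
  Calibration: 95% intervals for a Bernoulli(0.3) mean at n = 200 cover at
  ~95% (measured 95.8% over 1,000 simulations in the acceptance suite).
* **Spearman** as Pearson correlation of midranks (average ranks for ties);
  undefined (raises) on constant input.
* **Cohort percentiles** by the midrank rule,
  100·(#below + ties/2)/n, which makes "top 5% of its year" stable under
  tied citation counts.

## Enrichment scans

For a group (journal, funder, activity code, organization) and target class,
the 2×2 table counts target/non-target publications inside versus outside
the group, within the period's corpus of publications highlighting ≥1 gene.
Multi-group publications (several funders) count in each of their groups and
in no group's out-group twice. Fold enrichment uses the *corpus-wide* target
share (including the group) as denominator — this keeps the statistic
defined for arbitrarily large groups; a group with no target publications
reports a −∞ sentinel. Degenerate tables (no targets anywhere, or only
targets) carry no information and are reported with p = 1 rather than
aborting a scan, which permutation-null calibration relies on. Bonferroni m
is the number of groups actually tested (after the minimum-group-size
filter), per scan and per target class. The family-wise error of a full scan
under a permutation null measures ≤ 1% at α = 0.01 (acceptance suite,
1,000 permutations).

The *disproportionate-recent* rule compares linear fold ratios (not log₂
values): a group is flagged when fold_recent ≥ 2·fold_new; a −∞ new-side
sentinel (linear ratio 0) with a finite recent fold flags true.

## Field labels

A publication is **genome biology** when title, abstract, author keywords or
MeSH descriptor *names* contain any phrase of the packaged lexicon,
case-insensitively. A publication is a **GWAS** when it carries MeSH
descriptor code D055106, appears in a supplied association-catalog
identifier set, or matches the GWAS lexicon in title/abstract/keywords (MeSH
names are not consulted on this route). Matching is **token-bounded** by
default: a phrase matches only where delimited by non-alphanumeric
characters or string edges, because the lexica contain short tokens ("wes",
"ngs", "wgs") that would otherwise fire inside ordinary words ("western").
This is the one deliberate interpretation risk — raw containment is
config-selectable (`mode="substring"`) for sensitivity analysis. No
normalization beyond lowercasing is applied; hyphenated and spaced variants
are both listed in the lexica.

## Citation metrics

The citation graph is directed citing → cited with per-node year and
publication-type metadata; self-citations are dropped on load. Citation
totals may be supplied separately (including citers outside the loaded edge
list); such out-of-graph citers contribute to percentiles but not to
disruption classification. "Highly cited" means within-year midrank
percentile ≥ 95; cohorts under 20 publications are flagged low-cohort.
Clinical-trial matching is substring-based ("clinical trial" anywhere in a
publication-type string, case-folded). Citation-lag to the first trial citer
is floored at 0. The disruption index classifies every publication citing
the focal paper or ≥1 of its references (focal-year citers included, the
focal paper itself excluded); D = (n_focal−n_both)/(n_focal+n_both+n_ref) ∈
[−1, 1], undefined (absent) when no such citers exist. Disruption
percentiles are computed within publication-year cohorts, consistent with
the other percentile metrics. IQR widths of citation percentiles use
linear-interpolation quartiles between order statistics (so
[10, 40, 60, 90] → P25 = 32.5, P75 = 67.5, width 35).

## Concentration

Within a period, eligible genes are those occupying the recent class for ≥1
period year (first highlighted between period_start − 5 and period_end − 1);
eligible genes with zero recent pairs are retained, since "never taken up
again" is itself a result. Ranks sort by recent-pair count descending with
gene-identifier tie-breaks for determinism. The top set is the
ceil(fraction · eligible) top-ranked genes (1% of 3,943 eligible genes gives
exactly 40). The journal×gene matrix reports the percentage of a journal's
period publications (all of them in the filtered corpus, not only those
highlighting genes) that highlight each gene while recent; rows may sum past
100. Ward clustering uses Euclidean distances on the raw percentage cells,
applied to rows and columns independently, with Newick exports of both
trees. The ablation re-test removes all pairs on the top genes and re-runs
the recent-target scan, returning the groups that remain significantly
enriched.

## Synthetic corpus generator

The generator emits all five input tables with full internal consistency
(mention offsets resolve to the section the pair records; curated links
cover every pair; decoy reviews, ambiguous `;` mentions and non-coding /
wrong-taxon mentions exercise the filters without entering the ground
truth). Its defaults define the study conditions the recovery tests assume:

* 128 publications/year over 1980–2018 (~5,000 research publications after
  review decoys are filtered);
* novelty rate (probability that a publication introduces a never-
  highlighted gene) decaying exponentially from 0.60 to an asymptote of
  0.05 with a 3-year time constant — the early years seed the gene pools,
  the settled regime has the class mix 5% new / 15% recent / 80% old;
* gene reuse by preferential attachment, weight (pair count + 1)^1;
  additional genes per publication are always old-class, with class-
  dependent means (new 2, recent 1, old 0.5, capped), so the planted
  pair-level class mixture is analytically known (new share =
  0.05/1.65 ≈ 3.0%, recent 9.1%, old 87.9%);
* six journals with baseline probabilities (0.30, 0.20, 0.15, 0.15, 0.10,
  0.10) and recent-target multipliers (0.2, 0.2, 1, 1, 2, 4); the journal is
  drawn first and the recent-class probability is rate × multiplier. The
  probability-weighted multiplier sum is exactly 1, so each journal's
  corpus-denominator fold equals its multiplier in expectation and "recovered
  fold within CI of log₂(multiplier)" is well-posed;
* class-dependent team sizes (Poisson means 8 / 6 / 4 for new / recent /
  old);
* genome-biology labels injected as a lexicon keyword in 30% of
  publications, GWAS routes (phrase / MeSH / catalog) at 3% / 2% / 1% — the
  GWAS phrase and MeSH name both contain a genome-biology token, which the
  ground truth accounts for;
* a high-citation flag at 5% overall with class-relative boosts 2 : 1.5 : 1
  (new : recent : old), realised as well-separated citation-count
  distributions so the within-year top-5% cut recovers the flags. The planted
  5% overall rate holds exactly only in the settled regime (the warm-up
  years are over-flagged and the within-year cut trims them), so boost
  recovery is evaluated on 2000–2018;
* ~3 within-corpus references per publication (uniform over earlier
  publications) and a 5% clinical-trial publication-type rate, giving a
  citation graph for disruption and trial-citation metrics.

What the generator does **not** emulate: real gene-name ambiguity and
nomenclature drift, abstract-length variation, co-citation structure,
journal growth, correlated funders/organizations, or any fitted resemblance
to the real literature's marginals. Passing recovery tests therefore shows
that the pipeline's estimators are consistent and calibrated on data obeying
its assumptions — not that real-corpus estimates are unbiased.

Byte-for-byte determinism given (parameters, seed) is a contract and is
tested. Default sizes keep the full test suite around one to two minutes on
a single CPU; the parameter-recovery checks use the default ~5,000-
publication corpus, the structural tests a ~800-publication one.

## Numerical choices and degenerate inputs

Ties: ranks by gene identifier; percentiles by midrank; quartiles by linear
interpolation. Bootstrap seeds are derived deterministically from the run
seed (offset per window/decade so series cells are independent but
reproducible). Empty mention tables, empty scan results and empty ablations
return empty tables, not errors; empty registries, zero margins, constant
correlation inputs, all-zero weights and even windows raise. The pipeline
CLI distinguishes configuration errors (exit 2) from data errors (exit 3).

## Known limitations

* The headline shares of the real literature (fraction of genes ever
  highlighted, genome-biology shares, identities of the top genes) require
  full MEDLINE/PubTator/iCite snapshots and are outside this package's
  scope; the synthetic corpus is deliberately stylised.
* Token-bounded lexicon matching may differ from upstream raw-containment
  implementations on pathological inputs; the substring mode exists to
  quantify that difference.
* The bootstrap is percentile-only; no BCa or block variants.
* Funder co-occurrence and grant-level amounts are not modelled; the
  activity-code fiscal-share comparison is out of scope.
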