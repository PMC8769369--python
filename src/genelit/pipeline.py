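"""End-to-end pipeline: ingest -> ages -> classify -> enrich -> impact ->
concentration, with tidy TSV/JSON exports and a run manifest.

The run configuration is a flat mapping (usually loaded from YAML) naming the
input files and the analysis knobs; identical configuration and inputs yield
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import concentration, context_enrich, corpus_io, field_classify, gene_age
from . import impact_metrics

__all__ = ["RunConfig", "ConfigError", "DataError", "run_pipeline",
           "export_figure_tables"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (exit code 2 in the CLI)."""


class DataError(ValueError):
    """Inputs that parse but violate the pipeline's contracts (exit code 3)."""


_REQUIRED_INPUTS = ("publications", "mentions", "gene2pubmed", "gene_info")


@dataclass
class RunConfig:
    input_dir: Path
    out_dir: Path
    taxon: int = 9606
    year_max: int = 2018
    window: int = 3
    alpha: float = 0.01
    n_boot: int = 200
    seed: int = 0
    period: tuple[int, int] = (2010, 2018)
    top_fraction: float = 0.01
    min_group_size: int = 5
    classifier_mode: str = "token"
    catalog_pmids: frozenset = field(default_factory=frozenset)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: dict) -> "RunConfig":
        for key in ("input_dir", "out_dir"):
            if key not in raw:
                raise ConfigError(f"config missing required key {key!r}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**{**raw,
                     "input_dir": Path(raw["input_dir"]),
                     "out_dir": Path(raw["out_dir"]),
                     "period": tuple(raw.get("period", (2010, 2018))),
                     "catalog_pmids": frozenset(raw.get("catalog_pmids", ()))})
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.window % 2 == 0 or self.window < 1:
            raise ConfigError(f"window must be odd, got {self.window}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0,1), got {self.alpha}")
        if self.n_boot < 1:
            raise ConfigError("n_boot must be >= 1")
        for name in _REQUIRED_INPUTS:
            path = self.input_dir / f"{name}.tsv"
            if not path.exists():
                raise ConfigError(f"missing input file: {path}")

    def digest(self) -> str:
        payload = {k: sorted(v) if isinstance(v, frozenset) else
                   (str(v) if isinstance(v, Path) else v)
                   for k, v in self.__dict__.items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=list).encode()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the result bundle and writes TSV/JSON.

    The manifest records the configuration hash, seed and per-stage row
    counts, so reruns can be compared at a glance.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    # --- ingest
    try:
        records = corpus_io.read_publications(config.input_dir / "publications.tsv")
        mentions = corpus_io.read_mentions(config.input_dir / "mentions.tsv")
        links = corpus_io.read_gene_links(config.input_dir / "gene2pubmed.tsv")
        registry = corpus_io.read_gene_registry(config.input_dir / "gene_info.tsv")
    except corpus_io.FormatError as exc:
        raise DataError(f"ingest failed: {exc}") from exc
    records = corpus_io.filter_research_publications(records, config.year_max)
    pairs = corpus_io.build_highlight_table(records, mentions, links, registry,
                                            taxon=config.taxon)
    if len(pairs) == 0:
        raise DataError("no highlight pairs survived the filters")
    bundle["records"], bundle["pairs"] = records, pairs

    # --- ages
    age_table = gene_age.first_highlight_years(pairs)
    pairs = gene_age.assign_age_classes(pairs, age_table)
    bundle["age_table"], bundle["pairs"] = age_table, pairs
    years = range(int(pairs["pub_year"].min()), int(pairs["pub_year"].max()) + 1)
    bundle["cumulative_curve"] = gene_age.cumulative_highlight_curve(
        age_table, registry, years, taxon=config.taxon)
    bundle["pair_shares"] = gene_age.pair_share_series(
        pairs, window=config.window, n_boot=config.n_boot, seed=config.seed)
    bundle["enrichment_series"] = gene_age.category_enrichment_series(
        pairs, age_table, window=config.window, n_boot=config.n_boot,
        seed=config.seed)
    for metric in ("mean_authors", "mean_genes"):
        bundle[metric] = gene_age.decade_aggregate(
            records, pairs, metric=metric, n_boot=config.n_boot, seed=config.seed)

    # --- classify
    bundle["field_labels"] = field_classify.label_corpus(
        records, config.catalog_pmids, mode=config.classifier_mode)

    # --- enrich
    highlight_pmids = set(pairs["pmid"])
    start, end = config.period
    corpus_pmids = set(
        records.loc[records["year"].between(start, end), "pmid"]) & highlight_pmids
    membership = context_enrich.membership_from_records(records, "journal")
    period_pairs = pairs[pairs["pub_year"].between(start, end)]
    scans = {}
    for target in ("new", "recent"):
        targets = context_enrich.target_publications(period_pairs, target)
        scans[target] = context_enrich.enrichment_scan(
            corpus_pmids, targets, membership, alpha=config.alpha,
            min_group_size=config.min_group_size)
    bundle["scan_new"], bundle["scan_recent"] = scans["new"], scans["recent"]
    bundle["new_vs_recent"] = context_enrich.new_vs_recent_comparison(
        scans["new"], scans["recent"])

    # --- impact (optional inputs)
    cite_path = config.input_dir / "citations.tsv"
    if cite_path.exists():
        counts_path = config.input_dir / "citation_counts.tsv"
        counts = (pd.read_csv(counts_path, sep="\t")
                  if counts_path.exists() else None)
        graph = impact_metrics.load_citation_graph(cite_path, records, counts)
        bundle["highly_cited"] = impact_metrics.highly_cited_table(graph)
        bundle["disruption"] = impact_metrics.disruption_table(graph)
        bundle["graph"] = graph

    # --- concentration
    rank_table = concentration.rank_recent_targets(pairs, age_table, config.period)
    top_genes, top_share = concentration.top_set(rank_table, config.top_fraction)
    bundle["rank_table"] = rank_table
    bundle["top_genes"], bundle["top_share"] = top_genes, top_share
    flagged = bundle["new_vs_recent"]
    journals = flagged.loc[
        flagged["disproportionate_recent"].fillna(False), "group"].tolist()
    bundle["journal_topk_share"] = concentration.journal_topk_share(
        pairs, records, journals or list(membership["group"].unique()),
        top_genes, config.period)
    bundle["ablation"] = concentration.ablation_retest(
        pairs, records, membership, top_genes, config.period,
        alpha=config.alpha, min_group_size=config.min_group_size)

    # --- export
    manifest = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "rows": {k: int(len(v)) for k, v in bundle.items()
                 if isinstance(v, (pd.DataFrame, pd.Series, list))},
    }
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        elif isinstance(obj, pd.Series):
            obj.rename_axis("key").reset_index().to_csv(
                out / f"{name}.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    bundle["manifest"] = manifest
    return bundle


_FIGURE_SCHEMAS = {
    "fig1a": ("cumulative_curve", ["year", "share_highlighted", "share_title"]),
    "fig1b": ("pair_shares", ["center_year", "age_class", "share", "lo", "hi"]),
    "fig1c": ("enrichment_series", ["center_year", "age_class", "enrichment",
                                    "lo", "hi"]),
    "fig2a": ("mean_authors", ["decade", "age_class", "value", "lo", "hi", "n"]),
    "fig2b": ("mean_genes", ["decade", "age_class", "value", "lo", "hi", "n"]),
    "fig3c": ("new_vs_recent", ["group", "fold_new", "fold_recent",
                                "disproportionate_recent"]),
    "fig6a": ("rank_table", ["rank", "gene_id", "n_recent_pairs", "cum_share"]),
}


def export_figure_tables(bundle: dict, figure: str) -> pd.DataFrame:
    """Tidy table underlying one of the analysis figures."""
    if figure not in _FIGURE_SCHEMAS:
        raise ValueError(f"unknown figure label {figure!r}; "
                         f"known: {sorted(_FIGURE_SCHEMAS)}")
    key, columns = _FIGURE_SCHEMAS[figure]
    if key not in bundle:
        raise ValueError(f"bundle lacks stage output {key!r}")
    frame = bundle[key]
    return frame[columns].copy()
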