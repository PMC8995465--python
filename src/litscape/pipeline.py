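"""End-to-end orchestration: parse -> screen -> LDA -> network -> communities
-> trends, with every stage writing self-describing artifacts so later stages
(and the CLI subcommands) can re-run independently and idempotently.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from . import (
    community,
    lda_gibbs,
    pubmed_corpus,
    synthetic_data,
    text_prep,
    topic_net,
    trends,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """One artifact describing a full reproducible run.

    The top-level ``seed`` propagates to every stochastic stage (generator,
    sampler, community detection) unless a stage overrides it explicitly.
    """

    out_dir: str = "litscape_out"
    seed: int = 0
    input_xml: Optional[str] = None
    generator: dict[str, Any] = field(default_factory=dict)
    window: tuple[int, int] = (1996, 2021)
    excluded_types: Optional[list[str]] = None
    min_abstract_tokens: int = 50
    min_df: int = 5
    use_title: bool = False
    lda: dict[str, Any] = field(default_factory=dict)
    topic_labels: dict[int, str] = field(default_factory=dict)
    resolution: float = 1.0
    baseline_year: int = 1996
    mesh_terms: Optional[list[str]] = None
    top_k_countries: int = 10

    def validate(self) -> None:
        if self.min_abstract_tokens < 1:
            raise ValueError("min_abstract_tokens must be >= 1")
        if self.min_df < 1:
            raise ValueError("min_df must be >= 1")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if len(self.window) != 2 or self.window[1] < self.window[0]:
            raise ValueError("window must be (start_year, end_year)")
        if not self.window[0] <= self.baseline_year <= self.window[1]:
            raise ValueError("baseline_year must lie inside the window")
        if self.input_xml is not None and not Path(self.input_xml).exists():
            raise FileNotFoundError(self.input_xml)
        known = {f.name for f in dataclasses.fields(lda_gibbs.LdaConfig)}
        unknown = set(self.lda) - known
        if unknown:
            raise ValueError(f"unknown lda settings: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "window" in raw:
            raw["window"] = tuple(raw["window"])
        if "topic_labels" in raw:
            raw["topic_labels"] = {int(k): v for k, v in raw["topic_labels"].items()}
        config = cls(**raw)
        config.validate()
        return config

    def lda_config(self) -> lda_gibbs.LdaConfig:
        settings = dict(self.lda)
        settings.setdefault("seed", self.seed)
        return lda_gibbs.LdaConfig(**settings)

    def outpath(self, name: str) -> Path:
        out = Path(self.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        return out / name


# ---------------------------------------------------------------------------
# Stages (file-based, individually re-runnable)
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig) -> Path:
    gen_config = synthetic_data.GeneratorConfig(
        **{"seed": config.seed, **config.generator}
    )
    records, truth = synthetic_data.generate(gen_config)
    path = config.outpath("records.xml")
    synthetic_data.write_pubmed_xml(records, path)
    with open(config.outpath("truth.json"), "w") as fh:
        json.dump(
            {
                "K_true": gen_config.K_true,
                "expected_topic_prevalence": truth.expected_topic_prevalence.tolist(),
                "type_flagged": len(truth.type_flagged_pmids),
                "language_flagged": len(truth.language_flagged_pmids),
                "mesh_terms": {
                    t: {"topic": s.topic, "emergence_year": s.emergence_year}
                    for t, s in truth.mesh_terms.items()
                },
            },
            fh,
            indent=2,
        )
    logger.info("simulate: wrote %d records to %s", len(records), path)
    return path


def _input_records(config: PipelineConfig) -> list:
    source = config.input_xml or config.outpath("records.xml")
    records = pubmed_corpus.parse_pubmed_xml(str(source))
    logger.info("parse: %d records from %s", len(records), source)
    return records


def stage_filter(config: PipelineConfig) -> pubmed_corpus.FilterReport:
    records = _input_records(config)
    records = pubmed_corpus.filter_year_window(records, *config.window)
    initial = len(records)
    excluded = (
        frozenset(config.excluded_types)
        if config.excluded_types
        else pubmed_corpus.DEFAULT_EXCLUDED_TYPES
    )
    kept, n_type = pubmed_corpus.apply_type_filter(records, excluded)
    kept, n_lang = pubmed_corpus.apply_language_abstract_filter(
        kept, config.min_abstract_tokens
    )
    report = pubmed_corpus.FilterReport(
        initial_count=initial,
        removed_by_type=n_type,
        removed_by_language_or_abstract=n_lang,
        final_count=len(kept),
    )
    report.to_json(config.outpath("filter_report.json"))
    synthetic_data.write_pubmed_xml(kept, config.outpath("filtered.xml"))
    logger.info(
        "filter: %d -> -%d (type) -> -%d (language/abstract) -> %d",
        initial,
        n_type,
        n_lang,
        len(kept),
    )
    return report


def stage_fit(config: PipelineConfig) -> lda_gibbs.LdaModel:
    records = pubmed_corpus.parse_pubmed_xml(str(config.outpath("filtered.xml")))
    corpus = text_prep.build_corpus(
        records, min_df=config.min_df, use_title=config.use_title
    )
    corpus.vocab.to_csv(config.outpath("vocabulary.csv"))
    model = lda_gibbs.fit(corpus, config.lda_config())
    model.save(config.outpath("model"))
    pp = lda_gibbs.perplexity(model, corpus)
    logger.info(
        "fit: K=%d V=%d D=%d perplexity=%.2f",
        model.K,
        model.V,
        len(corpus),
        pp,
    )
    with open(config.outpath("fit_stats.json"), "w") as fh:
        json.dump({"perplexity": pp, "K": model.K, "V": model.V}, fh)
    return model


def stage_network(config: PipelineConfig):
    model = lda_gibbs.LdaModel.load(config.outpath("model"))
    assignments = topic_net.assign_topics(model.theta, model.doc_ids)
    with open(config.outpath("assignments.csv"), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["doc_id", "primary_topic", "secondary_topic", "primary_prob", "secondary_prob"]
        )
        for a in assignments:
            writer.writerow(
                [
                    a.doc_id,
                    a.primary_topic,
                    a.secondary_topic,
                    f"{a.primary_prob:.8g}",
                    f"{a.secondary_prob:.8g}",
                ]
            )
    network = topic_net.build_network(
        assignments, n_topics=model.K, labels=config.topic_labels
    )
    topic_net.export_graph(network, config.outpath("network.graphml"), "graphml")
    topic_net.export_graph(network, config.outpath("network.gexf"), "gexf")
    topic_net.write_edge_list(network, config.outpath("edges.csv"))
    logger.info(
        "network: %d nodes, %d edges, %d documents",
        network.number_of_nodes(),
        network.number_of_edges(),
        len(assignments),
    )
    return network


def stage_communities(config: PipelineConfig) -> dict:
    network = topic_net.import_graph(config.outpath("network.graphml"), "graphml")
    partition = community.louvain(
        network, seed=config.seed, resolution=config.resolution
    )
    q = (
        community.modularity(network, partition, resolution=config.resolution)
        if network.size(weight="weight") > 0
        else 0.0
    )
    with open(config.outpath("communities.csv"), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node", "community"])
        for node in sorted(partition):
            writer.writerow([node, partition[node]])
    logger.info(
        "communities: %d communities, Q=%.4f",
        len(set(partition.values())),
        q,
    )
    return {"partition": partition, "modularity": q}


def _load_assignments(config: PipelineConfig):
    out = []
    with open(config.outpath("assignments.csv"), newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                topic_net.TopicAssignment(
                    doc_id=row["doc_id"],
                    primary_topic=int(row["primary_topic"]),
                    secondary_topic=int(row["secondary_topic"]),
                    primary_prob=float(row["primary_prob"]),
                    secondary_prob=float(row["secondary_prob"]),
                )
            )
    return out


def stage_trends(config: PipelineConfig) -> dict:
    records = pubmed_corpus.parse_pubmed_xml(str(config.outpath("filtered.xml")))
    window = config.window
    counts = trends.annual_counts(records, window)
    counts.to_csv(config.outpath("annual_counts.csv"), header=["count"])
    mesh = trends.mesh_term_trends(records, terms=config.mesh_terms, window=window)
    mesh.counts.to_csv(config.outpath("mesh_counts.csv"))
    mesh.proportions.to_csv(config.outpath("mesh_proportions.csv"))
    emerging = trends.emerging_terms(mesh, config.baseline_year)
    shares = trends.country_shares(records)
    shares.to_csv(config.outpath("country_shares.csv"), index=False)
    summary = {
        "total_publications": int(counts.sum()),
        "mean_annual": trends.mean_annual(int(counts.sum()), len(counts)),
        "avg_growth_rate": (
            trends.avg_growth_rate(counts.values)
            if (counts.values[:-1] > 0).all() and len(counts) > 1
            else None
        ),
        "linear_trend": trends.linear_trend(counts.values),
        "emerging_terms": emerging,
        "top_countries": shares.head(config.top_k_countries).to_dict("records"),
        "top_k_country_share": (
            trends.top_k_share(shares, config.top_k_countries)
            if len(records)
            else 0.0
        ),
    }
    assignments_path = config.outpath("assignments.csv")
    if assignments_path.exists():
        assignments = _load_assignments(config)
        year_of = {r.pmid: r.year for r in records}
        aligned = [a for a in assignments if a.doc_id in year_of]
        heatmap = trends.topic_year_heatmap(
            aligned, [year_of[a.doc_id] for a in aligned], window
        )
        heatmap.to_csv(config.outpath("topic_year_heatmap.csv"))
        summary["heatmap_total"] = int(heatmap.values.sum())
    with open(config.outpath("trend_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    logger.info("trends: %d publications in window", summary["total_publications"])
    return summary


def stage_report(config: PipelineConfig) -> dict:
    """Assemble per-stage artifacts into one summary JSON."""
    summary: dict[str, Any] = {"seed": config.seed}
    report_path = config.outpath("filter_report.json")
    if report_path.exists():
        report = pubmed_corpus.FilterReport.from_json(report_path)
        summary["filter_report"] = dataclasses.asdict(report)
    for name in ("fit_stats", "trend_summary"):
        path = config.outpath(f"{name}.json")
        if path.exists():
            with open(path) as fh:
                summary[name] = json.load(fh)
    communities_path = config.outpath("communities.csv")
    if communities_path.exists():
        with open(communities_path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        summary["n_communities"] = len({r["community"] for r in rows})
    path = config.outpath("summary.json")
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("report: wrote %s", path)
    return summary


_STAGES = {
    "simulate": stage_simulate,
    "filter": stage_filter,
    "fit": stage_fit,
    "network": stage_network,
    "communities": stage_communities,
    "trends": stage_trends,
    "report": stage_report,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns the assembled summary.

    When ``input_xml`` is set the simulate stage is skipped and the given
    corpus is used instead.  Any stage failure propagates with the stage name
    attached.
    """
    config.validate()
    order = ["simulate", "filter", "fit", "network", "communities", "trends", "report"]
    if config.input_xml is not None:
        order = order[1:]
    result: dict = {}
    for name in order:
        try:
            result = _STAGES[name](config)  # type: ignore[operator]
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return result if isinstance(result, dict) else {}
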