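"""End-to-end orchestration: normalize -> seeds -> cosine -> candidates ->
clusters -> enrichment, with deterministic TSV outputs and a run manifest.

Every stage writes a plain TSV so each step can be re-run or inspected
independently; the manifest records every threshold used so no numeric
constant is hidden. The per-comparison summary mirrors the screen's three
headline counts: differentially expressed seeds, distinct co-regulated tail
probes, and candidates supported by at least ``min_seed_support`` seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import candidates_clusters, cosine_engine, enrichment, io_formats, preprocess, seeds
from .io_formats import ExpressionMatrix, write_table
from .synthetic_data import SimulationConfig, simulate

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds and paths for one run (CLI flags override YAML keys)."""

    matrix_path: str | None = None
    design_path: str | None = None
    gmt_path: str | None = None
    probe_gene_map_path: str | None = None
    out_dir: str = "cosreg_run"
    input_scale: str = "log2"  # or "linear": apply log2(x + 1) on load
    quantile_normalize: bool = True
    center: bool = True
    pooled_tails: bool = False
    fold_threshold: float = 5.0
    tail_fraction: float = 0.005
    min_seed_support: int = 10
    alpha: float = 0.05
    universe_size: int | None = None
    simulate: bool = False
    sim: SimulationConfig | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        sim_raw = raw.pop("sim", None)
        config = cls(**raw)
        if sim_raw is not None:
            config.sim = SimulationConfig(**sim_raw)
        return config

    def thresholds(self) -> dict:
        return {
            "input_scale": self.input_scale,
            "quantile_normalize": self.quantile_normalize,
            "center": self.center,
            "pooled_tails": self.pooled_tails,
            "fold_threshold": self.fold_threshold,
            "tail_fraction": self.tail_fraction,
            "min_seed_support": self.min_seed_support,
            "alpha": self.alpha,
            "universe_size": self.universe_size,
        }


@dataclass
class PipelineResult:
    """In-memory results plus the on-disk manifest of one pipeline run."""

    summary: pd.DataFrame
    seed_sets: dict
    tables: dict
    candidates: dict
    clusters: dict
    enrichment: dict
    ranking: pd.DataFrame | None
    truth: object | None
    manifest: dict


def _load_matrix(config: PipelineConfig):
    if config.simulate:
        sim = config.sim or SimulationConfig()
        matrix, truth = simulate(sim)
        return matrix, truth
    if config.matrix_path is None or config.design_path is None:
        raise ValueError("matrix_path and design_path are required unless simulate=true")
    matrix = io_formats.read_expression_tsv(config.matrix_path, config.design_path)
    return matrix, None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage, writing per-stage TSVs and a manifest under out_dir.

    Stage failures abort with the stage name and cause. Reruns with the same
    config and inputs produce byte-identical outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"thresholds": config.thresholds(), "stages": {}, "outputs": {}}

    stage = "load"
    try:
        matrix, truth = _load_matrix(config)
        if config.input_scale == "linear":
            frame = np.log2(matrix.data + 1.0)
            matrix = ExpressionMatrix(frame, matrix.design)
        elif config.input_scale != "log2":
            raise ValueError(f"unknown input_scale {config.input_scale!r}")
        manifest["stages"]["load"] = {
            "n_probes": matrix.n_probes, "n_samples": matrix.n_samples,
        }
        if truth is not None:
            truth_path = out_dir / "truth.tsv"
            write_table(truth.to_frame(), truth_path, kind="truth")
            manifest["outputs"]["truth"] = truth_path.name
            io_formats.write_expression_tsv(
                matrix, out_dir / "matrix.tsv", out_dir / "design.tsv"
            )
            manifest["outputs"]["matrix"] = "matrix.tsv"
            manifest["outputs"]["design"] = "design.tsv"

        stage = "normalize"
        if config.quantile_normalize:
            matrix = preprocess.quantile_normalize(matrix)
        means = preprocess.group_means(matrix)

        stage = "seeds"
        seed_sets = {
            comparison.id: seeds.select_seeds(means, comparison, config.fold_threshold)
            for comparison in seeds.CANONICAL_COMPARISONS
        }
        seeds_path = out_dir / "seeds.tsv"
        write_table(seeds.seeds_to_frame(seed_sets), seeds_path, kind="seeds")
        manifest["outputs"]["seeds"] = seeds_path.name

        stage = "cosine"
        tables, histograms = {}, []
        for comparison_id, seed_set in seed_sets.items():
            table = cosine_engine.similarity_table(
                matrix,
                seed_set,
                tail_fraction=config.tail_fraction,
                center=config.center,
                pooled_tails=config.pooled_tails,
            )
            tables[comparison_id] = table
            histograms.append(cosine_engine.cosine_histogram(table).to_frame())
        tails_frame = pd.concat(
            [t.to_tail_frame() for t in tables.values()], ignore_index=True
        )
        tails_path = out_dir / "similarity_tails.tsv"
        write_table(tails_frame, tails_path, kind="similarity_tails")
        manifest["outputs"]["similarity_tails"] = tails_path.name
        hist_path = out_dir / "cosine_histograms.tsv"
        write_table(
            pd.concat(histograms, ignore_index=True), hist_path,
            kind="support_distribution",
        )
        manifest["outputs"]["cosine_histograms"] = hist_path.name

        stage = "candidates"
        candidate_lists, support_frames, candidate_frames = {}, [], []
        for comparison_id, table in tables.items():
            candidate_list = candidates_clusters.build_candidates(
                table, min_seed_support=config.min_seed_support
            )
            candidate_lists[comparison_id] = candidate_list
            frame = candidate_list.table.copy()
            frame.insert(0, "comparison", comparison_id)
            candidate_frames.append(frame)
            support_frames.append(candidates_clusters.support_distribution(table))
        candidates_path = out_dir / "candidates.tsv"
        write_table(
            pd.concat(candidate_frames, ignore_index=True), candidates_path,
            kind="candidates",
        )
        manifest["outputs"]["candidates"] = candidates_path.name
        support_path = out_dir / "support_distribution.tsv"
        write_table(
            pd.concat(support_frames, ignore_index=True), support_path,
            kind="support_distribution",
        )
        manifest["outputs"]["support_distribution"] = support_path.name

        stage = "clusters"
        cluster_map = {
            comparison_id: candidates_clusters.build_clusters(
                tables[comparison_id], candidate_lists[comparison_id]
            )
            for comparison_id in tables
        }
        cluster_frames = [
            candidates_clusters.clusters_to_frame(clusters)
            for clusters in cluster_map.values()
        ]
        clusters_path = out_dir / "clusters.tsv"
        write_table(
            pd.concat(cluster_frames, ignore_index=True), clusters_path, kind="clusters"
        )
        manifest["outputs"]["clusters"] = clusters_path.name

        stage = "enrichment"
        enrichment_results: dict = {}
        ranking = None
        if config.gmt_path is not None:
            universe_size = config.universe_size or matrix.n_probes
            collection = io_formats.read_gmt(config.gmt_path, universe_size)
            mapping = (
                io_formats.read_probe_gene_map(config.probe_gene_map_path)
                if config.probe_gene_map_path
                else {}
            )
            for comparison_id in tables:
                query = set(seed_sets[comparison_id].probe_ids) | set(
                    candidate_lists[comparison_id].probe_ids
                )
                query = {mapping.get(p, p) for p in query}
                if not query:
                    logger.warning("no query genes for %s; enrichment skipped", comparison_id)
                    continue
                enrichment_results[comparison_id] = enrichment.enrich(
                    query, collection, alpha=config.alpha, comparison_id=comparison_id
                )
            if enrichment_results:
                enrichment_path = out_dir / "enrichment.tsv"
                write_table(
                    pd.concat(enrichment_results.values(), ignore_index=True),
                    enrichment_path,
                    kind="enrichment",
                )
                manifest["outputs"]["enrichment"] = enrichment_path.name
                ranking = enrichment.rank_pathways(enrichment_results, alpha=config.alpha)
                ranking_path = out_dir / "pathway_ranking.tsv"
                write_table(ranking, ranking_path, kind="ranking")
                manifest["outputs"]["pathway_ranking"] = ranking_path.name

        stage = "summary"
        summary = pd.DataFrame(
            {
                "comparison": list(tables),
                "n_seeds": [len(seed_sets[c]) for c in tables],
                "n_coregulated_probes": [len(tables[c].tail_members()) for c in tables],
                "n_candidates": [len(candidate_lists[c]) for c in tables],
            }
        )
        summary_path = out_dir / "summary.tsv"
        write_table(summary, summary_path, kind="summary")
        manifest["outputs"]["summary"] = summary_path.name
        manifest["stages"]["summary"] = summary.to_dict(orient="records")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    logger.info("pipeline finished; manifest at %s", manifest_path)

    return PipelineResult(
        summary=summary,
        seed_sets=seed_sets,
        tables=tables,
        candidates=candidate_lists,
        clusters=cluster_map,
        enrichment=enrichment_results,
        ranking=ranking,
        truth=truth,
        manifest=manifest,
    )
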