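"""End-to-end orchestration: composition -> DE -> panel sweep -> targets ->
enrichment, with a reproducibility manifest.

A run either loads a count matrix and sample sheet from disk or simulates
them; edge lists and annotations are likewise loaded or simulated. Every
output is TSV/JSON, and the manifest records parameters, the seed, and a
SHA-256 checksum of every written artifact so identical configurations can
be verified to reproduce identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .de import run_de, summarize_de, volcano_classes, zscore_matrix, pca_variance, compute_cpm, tmm_factors, filter_low_expression
from .enrichment import hypergeom_enrichment, level_filter
from .panel import ClassifierConfig, sweep_panel_sizes
from .synthetic import (
    SimulationConfig,
    simulate_annotations,
    simulate_biotypes,
    simulate_counts,
    simulate_edge_lists,
    simulate_ontology,
)
from .targets import aggregate_targets, disease_target_sets, load_edge_lists

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("seramir")

ALL_STAGES = ("data", "compose", "de", "panel", "targets", "enrich")


@dataclass
class PipelineConfig:
    outdir: str = "seramir_out"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # data acquisition: file paths take precedence over simulation
    counts_path: str | None = None
    samples_path: str | None = None
    biotypes_path: str | None = None
    edge_list_paths: list[str] = field(default_factory=list)
    annotation_path: str | None = None
    ontology_path: str | None = None
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides
    # stage parameters
    de_params: dict = field(default_factory=dict)  # min_cpm, min_libraries, prior_df
    p_thresh: float = 0.05
    lfc_thresh: float = 1.0
    panel_params: dict = field(default_factory=dict)  # start, step, patience, max_size
    classifier: dict = field(default_factory=dict)  # ClassifierConfig overrides
    db_thresholds: dict = field(default_factory=dict)
    default_db_threshold: float = 0.6
    target_cap: int = 50
    min_level: int = 4
    max_level: int = 16
    # simulated auxiliary fixtures when paths are absent
    sim_edges: dict = field(default_factory=lambda: {"n_genes": 300, "n_databases": 3, "density": 0.02})


def load_config(path) -> PipelineConfig:
    """Read a pipeline configuration from a YAML or JSON file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "stages" in data:
        data["stages"] = tuple(data["stages"])
    return PipelineConfig(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Run:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.artifacts: dict[str, str] = {}

    def write_df(self, name: str, df: pd.DataFrame, index: bool = False) -> Path:
        path = self.outdir / name
        df.to_csv(path, sep="\t", index=index)
        self.artifacts[name] = _sha256(path)
        return path

    def write_json(self, name: str, obj) -> Path:
        path = self.outdir / name
        path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
        self.artifacts[name] = _sha256(path)
        return path


def _check_inputs(config: PipelineConfig) -> None:
    for attr in ("counts_path", "samples_path", "biotypes_path", "annotation_path", "ontology_path"):
        p = getattr(config, attr)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"{attr} does not exist: {p}")
    for p in config.edge_list_paths:
        if not Path(p).exists():
            raise FileNotFoundError(f"edge list does not exist: {p}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages in order and return the run manifest."""
    _check_inputs(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run = _Run(outdir)
    manifest: dict = {
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "stages_run": [],
        "inputs": {},
    }

    # ----- data -----------------------------------------------------------
    truth: dict[str, float] = {}
    if config.counts_path:
        counts = sio.read_count_matrix(config.counts_path)
        if not config.samples_path:
            raise ValueError("samples_path is required when counts_path is given")
        sheet = sio.read_sample_sheet(config.samples_path)
        manifest["inputs"]["counts"] = _sha256(Path(config.counts_path))
        manifest["inputs"]["samples"] = _sha256(Path(config.samples_path))
    else:
        sim_cfg = SimulationConfig(**{"seed": config.seed, **config.simulate})
        dataset = simulate_counts(sim_cfg)
        counts, sheet, truth = dataset.counts, dataset.sample_sheet, dataset.truth
        path = outdir / "counts.tsv"
        sio.write_count_matrix(counts, path)
        run.artifacts["counts.tsv"] = _sha256(path)
        run.write_df("samples.tsv", sheet)
        run.write_df(
            "truth.tsv",
            pd.DataFrame(sorted(truth.items()), columns=["mirna_id", "log2fc"]),
        )
    manifest["stages_run"].append("data")
    log.info("data: %d miRNAs x %d samples", *counts.shape)

    # ----- composition -----------------------------------------------------
    if "compose" in config.stages:
        if config.biotypes_path:
            biotypes = sio.read_biotypes(config.biotypes_path)
        else:
            biotypes = simulate_biotypes(list(counts.mirnas), seed=config.seed)
        grouping = sheet.set_index("sample_id")["group"]
        comp = sio.composition_report(counts, biotypes, grouping)
        run.write_df("composition.tsv", comp.reset_index())
        manifest["stages_run"].append("compose")

    # ----- differential expression -----------------------------------------
    de = None
    if "de" in config.stages:
        de = run_de(counts, sheet, **config.de_params)
        table = de.sorted().reset_index(names="mirna_id")
        run.write_df("de_table.tsv", table)
        summary = summarize_de(de, p_thresh=config.p_thresh, lfc_thresh=config.lfc_thresh)
        run.write_json("de_summary.json", dataclasses.asdict(summary))
        run.write_df(
            "volcano.tsv",
            volcano_classes(de, config.p_thresh, config.lfc_thresh)
            .rename_axis("mirna_id")
            .reset_index(),
        )
        # Z-score matrix of the top miRNAs by p-value on normalized log-CPM
        filtered = filter_low_expression(counts, **{
            k: v for k, v in config.de_params.items() if k in ("min_cpm", "min_libraries")
        })
        norm = tmm_factors(filtered)
        top = de.sorted().index[:30]
        top = [m for m in top if m in filtered.counts.index]
        logcpm = np.log2(compute_cpm(filtered, norm).loc[top] + 0.5)
        run.write_df("zscore.tsv", zscore_matrix(logcpm), index=True)
        pct = pca_variance(logcpm if len(top) >= 2 else np.log2(compute_cpm(filtered, norm) + 0.5))
        run.write_json("pca_variance.json", {"percent_variance": list(pct)})
        manifest["stages_run"].append("de")
        log.info("de: %d tested, %d significant", summary.n_tested, summary.n_significant)

    # ----- panel sweep ------------------------------------------------------
    sweep = None
    if "panel" in config.stages:
        clf_cfg = ClassifierConfig(**config.classifier)
        sweep = sweep_panel_sizes(counts, sheet, config=clf_cfg, **config.panel_params)
        run.write_df(
            "sweep_trace.tsv",
            pd.DataFrame(sweep.saturation_trace, columns=["panel_size", "accuracy"]),
        )
        opt = sweep.optimal_metrics
        run.write_df(
            "fold_records.tsv",
            pd.DataFrame(
                [
                    {
                        "held_out": r.held_out,
                        "true_label": r.true_label,
                        "predicted": r.predicted,
                        "score": r.score,
                        "selected": ";".join(r.selected),
                    }
                    for r in opt.folds
                ]
            ),
        )
        run.write_df(
            "pooled_panel.tsv",
            pd.DataFrame(sorted(sweep.pooled_unique_mirnas), columns=["mirna_id"]),
        )
        run.write_json(
            "panel_metrics.json",
            {
                "optimal_size": sweep.optimal_size,
                "pooled_unique": len(sweep.pooled_unique_mirnas),
                "accuracy": opt.accuracy,
                "sensitivity": opt.sensitivity,
                "specificity": opt.specificity,
                "mcc": opt.mcc,
                "auc": opt.auc,
            },
        )
        from .panel import roc_auc as _roc

        _, roc_points = _roc([r.score for r in opt.folds], [r.true_label for r in opt.folds])
        run.write_df("roc_points.tsv", roc_points)
        manifest["stages_run"].append("panel")
        log.info("panel: optimal size %d, AUC %.3f", sweep.optimal_size, opt.auc)

    # ----- targets ----------------------------------------------------------
    agg = None
    population_genes: set[str] = set()
    if "targets" in config.stages:
        if config.edge_list_paths:
            edges = load_edge_lists(
                config.edge_list_paths, config.db_thresholds, config.default_db_threshold
            )
            for p in config.edge_list_paths:
                manifest["inputs"][Path(p).name] = _sha256(Path(p))
        else:
            tables = simulate_edge_lists(
                n_mirnas=counts.shape[0], seed=config.seed, **config.sim_edges
            )
            # simulated scores are uniform; keep everything above a mid threshold
            edges = load_edge_lists(tables, {}, 0.5)
        panel_mirnas = (
            sweep.pooled_unique_mirnas if sweep is not None else set(counts.mirnas)
        )
        edges_panel = edges[edges["mirna_id"].isin(panel_mirnas)]
        if edges_panel.empty:
            edges_panel = edges
        agg = aggregate_targets(edges_panel, cap=config.target_cap)
        run.write_df("aggregated_targets.tsv", agg)
        population_genes = set(edges["gene_id"])
        manifest["stages_run"].append("targets")
        log.info("targets: %d aggregated pairs", len(agg))

    # ----- enrichment -------------------------------------------------------
    if "enrich" in config.stages and agg is not None and len(agg):
        study = sorted(set(agg["gene_id"]))
        population = sorted(population_genes | set(study))
        if config.annotation_path:
            annotation = pd.read_csv(config.annotation_path, sep="\t")
            manifest["inputs"]["annotation"] = _sha256(Path(config.annotation_path))
        else:
            annotation = simulate_annotations(population, n_terms=60, seed=config.seed)
        if config.ontology_path:
            ontology = pd.read_csv(config.ontology_path, sep="\t")
        else:
            ontology = simulate_ontology(sorted(set(annotation["term_id"])), seed=config.seed)
        result = hypergeom_enrichment(study, annotation, population)
        kept = set(
            level_filter(result["term_id"], ontology, config.min_level, config.max_level)
        )
        result["within_levels"] = result["term_id"].isin(kept)
        run.write_df("enrichment.tsv", result)
        manifest["stages_run"].append("enrich")
        log.info("enrich: %d terms tested", len(result))

    manifest["artifacts"] = run.artifacts
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return manifest
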