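"""Stage orchestration: simulate -> quantify -> score -> classify -> network -> glyco.

Each stage reads the previous stage's TSV outputs (so stages are
independently runnable) and writes its own through :mod:`aapl.quant_io`.
The whole pipeline is deterministic given the config seed; the manifest
maps stage names to written files.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd

from . import classify, glyco, network, oxidation, quant_io, scoring, synthetic_data
from .config import PipelineConfig

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrap with the stage name
                raise StageError(name, exc) from exc
            return out
        wrapper.__name__ = fn.__name__
        wrapper.__doc__ = fn.__doc__
        return wrapper
    return deco


@_stage("simulate")
def run_simulate(config: PipelineConfig, out_dir: Path) -> dict[str, Path]:
    """Generate a ground-truthed synthetic experiment and write its input files."""
    params = dataclasses.replace(config.simulation, seed=config.seed)
    proteome = synthetic_data.generate_proteome(params)
    truth = synthetic_data.assign_ground_truth(proteome, params)
    table = synthetic_data.simulate_experiment(proteome, truth, config.design, params)
    edges = synthetic_data.simulate_string_edges(
        truth, config.string_overlap_fraction, config.n_decoy_edges, seed=config.seed
    )
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {
        "peptide_table": quant_io.write_peptide_table(table, out_dir / "peptides.tsv"),
        "string_links": quant_io.write_string_links(edges, out_dir / "string_links.tsv"),
        "fasta": quant_io.write_fasta(proteome, out_dir / "proteome.fasta"),
    }
    truth_table = synthetic_data.ground_truth_table(truth)
    files.update(
        (name, path)
        for name, path in zip(
            ["ground_truth"], quant_io.write_results({"ground_truth": truth_table}, out_dir)
        )
    )
    logger.info("simulate: %d peptide rows, %d edges", len(table), len(edges))
    return files


@_stage("quantify")
def run_quantify(config: PipelineConfig, out_dir: Path, peptide_path: Path) -> dict[str, Path]:
    """Site degrees, EPO profiles, condition matrix and clustering."""
    measurements = quant_io.read_peptide_table(peptide_path)
    profiles = oxidation.protein_profiles(measurements, config.design)
    sites = oxidation.site_table(measurements)
    matrix, leaf_order, _ = oxidation.condition_matrix_and_clustering(profiles)
    tables = {
        "protein_profiles": profiles,
        "site_degrees": sites,
        "epo_matrix": matrix.reset_index(),
        "condition_order": pd.DataFrame({"condition": leaf_order}),
    }
    regions = None
    if config.regions:
        regions = quant_io.read_region_table(config.regions)
    tables["region_summary"] = oxidation.map_sites_to_regions(sites, regions)
    manifest = quant_io.write_results(tables, out_dir)
    logger.info("quantify: %d measurement rows -> %d profiles", len(measurements), len(profiles))
    return {p.stem: p for p in manifest}


@_stage("score")
def run_score(config: PipelineConfig, out_dir: Path, profiles_path: Path) -> dict[str, Path]:
    """AAPL scores from the TopS transform of the spectral-count x EPO matrix."""
    profiles = pd.read_csv(profiles_path, sep="\t")
    matrix = scoring.build_score_matrix(profiles, mode=config.scoring_mode)
    tops_matrix = scoring.tops(matrix, rescale_total=config.rescale_total)
    scores = scoring.aapl_scores(tops_matrix, config.design.selected_condition)
    table = scoring.score_table(matrix, tops_matrix, config.design.selected_condition)
    manifest = quant_io.write_results(
        {
            "score_cells": table,
            "aapl_scores": scores.rename_axis("protein_id").reset_index(),
        },
        out_dir,
    )
    logger.info("score: %d proteins scored", len(scores))
    return {p.stem: p for p in manifest}


@_stage("classify")
def run_classify(
    config: PipelineConfig,
    out_dir: Path,
    profiles_path: Path,
    scores_path: Path,
    links_path: Path,
    bait_id: str,
) -> dict[str, Path]:
    """L1/L2 level calls, STRING typing, and the summary statistics."""
    profiles = pd.read_csv(profiles_path, sep="\t")
    scores = pd.read_csv(scores_path, sep="\t").set_index("protein_id")["aapl_score"]
    edges = quant_io.read_string_links(links_path, score_floor=config.score_floor)
    results = classify.build_results(
        scores, profiles, edges, bait_id, config.design.selected_condition, config.thresholds
    )
    bins = classify.mean_sites_by_score_bin(results)
    dist = classify.score_distribution_of_known_interactors(results)
    summary = pd.DataFrame(
        {
            "statistic": [f"mean_sites[{k}]" for k in bins]
            + [f"t1t2_fraction[{k}]" for k in (dist or {})],
            "value": list(bins.values()) + list((dist or {}).values()),
        }
    )
    manifest = quant_io.write_results({"interactors": results, "summary": summary}, out_dir)
    n_l1 = int((results["level"] == "L1").sum())
    n_l2 = int((results["level"] == "L2").sum())
    logger.info("classify: %d proteins -> %d L1, %d L2", len(results), n_l1, n_l2)
    return {p.stem: p for p in manifest}


@_stage("network")
def run_network(
    config: PipelineConfig, out_dir: Path, results_path: Path, links_path: Path, bait_id: str
) -> dict[str, Path]:
    """Annotated interaction graph written as GraphML, SIF, and attribute tables."""
    results = pd.read_csv(results_path, sep="\t")
    edges = quant_io.read_string_links(links_path, score_floor=config.score_floor)
    graph = network.build_network(results, edges, bait_id)
    files = {
        "graphml": quant_io.write_graphml(graph, out_dir / "network.graphml"),
        "sif": quant_io.write_sif(graph, out_dir / "network.sif"),
    }
    manifest = quant_io.write_results(
        {"network_nodes": network.node_table(graph), "network_edges": network.edge_table(graph)},
        out_dir,
    )
    files.update({p.stem: p for p in manifest})
    logger.info(
        "network: %d nodes, %d edges", graph.number_of_nodes(), graph.number_of_edges()
    )
    return files


@_stage("glyco")
def run_glyco(
    config: PipelineConfig, out_dir: Path, glyco_path: Path, results_path: Path | None
) -> dict[str, Path]:
    """Glycan typing and per-protein summaries for every protein in the glyco table."""
    records = quant_io.read_glyco_table(glyco_path)
    typed = glyco.classify_table(records)
    summaries = []
    for pid in sorted(typed["protein_id"].unique()):
        summary = glyco.glyco_summary(records, pid)
        if summary is not None:
            summaries.append(summary)
    summary_table = (
        pd.concat(summaries, ignore_index=True)
        if summaries
        else pd.DataFrame(columns=["protein_id", "glyco_type", "total", "percent"])
    )
    manifest = quant_io.write_results(
        {"glycopeptides_typed": typed, "glyco_summary": summary_table}, out_dir
    )
    logger.info("glyco: %d records over %d proteins", len(typed), typed["protein_id"].nunique())
    return {p.stem: p for p in manifest}


def run_pipeline(config: PipelineConfig) -> dict[str, dict[str, Path]]:
    """Run every stage in order; returns {stage: {output name: path}}."""
    out_dir = Path(config.out_dir)
    manifest: dict[str, dict[str, Path]] = {}

    if config.peptide_table is None:
        manifest["simulate"] = run_simulate(config, out_dir)
        peptide_path = manifest["simulate"]["peptide_table"]
        links_path = manifest["simulate"]["string_links"]
        truth = pd.read_csv(out_dir / "ground_truth.tsv", sep="\t")
        bait_id = str(truth.loc[truth["class"] == "bait", "protein_id"].iloc[0])
    else:
        peptide_path = Path(config.peptide_table)
        if config.string_links is None:
            raise StageError("classify", ValueError("string_links required with a peptide_table"))
        links_path = Path(config.string_links)
        if config.bait_id is None:
            raise StageError("classify", ValueError("bait_id required with a peptide_table"))
        bait_id = config.bait_id

    manifest["quantify"] = run_quantify(config, out_dir, peptide_path)
    manifest["score"] = run_score(config, out_dir, manifest["quantify"]["protein_profiles"])
    manifest["classify"] = run_classify(
        config,
        out_dir,
        manifest["quantify"]["protein_profiles"],
        manifest["score"]["aapl_scores"],
        links_path,
        bait_id,
    )
    manifest["network"] = run_network(
        config, out_dir, manifest["classify"]["interactors"], links_path, bait_id
    )
    if config.glyco_table is not None:
        manifest["glyco"] = run_glyco(
            config, out_dir, Path(config.glyco_table), manifest["classify"]["interactors"]
        )
    return manifest
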