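"""End-to-end pipeline orchestration.

``run_pipeline`` wires the stages together in the analysis order —
quantify -> replicate QC -> differential expression -> clustering and
enrichment -> pathway perturbation -> complex co-regulation — writing every
intermediate table under the output directory plus a machine-readable
``manifest.json`` (package version, parameters, seed, per-stage row counts,
and a SHA-256 digest of every artifact).  Two runs with the same config are
byte-identical, manifest included.

Inputs come either from files (intensity matrix + metadata, optionally
FASTA/PSM counts for the ppm route) or from the built-in simulator via a
``simulate`` config block, in which case the planted complexes and
trajectory classes double as annotation catalogs so the whole pipeline is
exercised without external data.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, cluster as cl, coregulation as cr, diffexp as de
from . import io as bio
from . import pathway as pw
from . import qc, quantify as qt
from .containers import AbundanceMatrix, ConfigurationError, SampleMetadata
from .coregulation import ComplexCatalog
from .synthetic import (
    BatchShift,
    ComplexPlan,
    SimulationConfig,
    TrajectoryClass,
    simulate_timecourse,
)

logger = logging.getLogger(__name__)

#: Analysis parameters mirroring the standard workflow defaults: tryptic
#: peptides of 7-40 residues, >=2 unique peptides, BH FDR 5%, |log2FC| >= 1,
#: two-fold trajectory filter, average linkage on correlation distance,
#: node-depth 3 cut with >500-member clusters re-cut at depth 5.
WORKFLOW_DEFAULTS: dict[str, Any] = {
    "filters": {
        "peptide_min_len": 7,
        "peptide_max_len": 40,
        "min_unique_peptides": 2,
        "fdr": 0.05,
        "min_log2fc": 1.0,
        "twofold": 1.0,
    },
    "clustering": {
        "depth": 3,
        "subset_threshold": 500,
        "subset_depth": 5,
        "metric": "correlation",
        "linkage": "average",
    },
    "diffexp": {"scheme": "all"},
}


def load_config(path: str | Path) -> dict[str, Any]:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    return merge_defaults(cfg)


def merge_defaults(cfg: dict[str, Any]) -> dict[str, Any]:
    out = json.loads(json.dumps(WORKFLOW_DEFAULTS))
    for key, value in cfg.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key].update(value)
        else:
            out[key] = value
    return out


def simulation_config_from_dict(block: dict[str, Any], seed: int) -> SimulationConfig:
    kwargs: dict[str, Any] = {"seed": seed}
    for key in ("n_proteins", "n_replicates", "replicate_noise_sd", "dropout_rate",
                "dropout_mode", "complex_amplitude"):
        if key in block:
            kwargs[key] = block[key]
    if "base_log_abundance" in block:
        kwargs["base_log_abundance"] = tuple(block["base_log_abundance"])
    if "time_points" in block:
        kwargs["time_points"] = [tuple(tp) for tp in block["time_points"]]
    if "trajectory_classes" in block:
        kwargs["trajectory_classes"] = [TrajectoryClass(*tc) for tc in block["trajectory_classes"]]
    if "batch_shifts" in block:
        kwargs["batch_shifts"] = [BatchShift(*bs) for bs in block["batch_shifts"]]
    if "complex_plan" in block:
        kwargs["complex_plan"] = [ComplexPlan(*cp) for cp in block["complex_plan"]]
    return SimulationConfig(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict[str, Any], output_dir: str | Path | None = None) -> dict[str, Any]:
    """Execute the full analysis described by ``config``; returns the manifest."""
    config = merge_defaults(config)
    outdir = Path(output_dir or config.get("output_dir", "brewtime_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    filters = config["filters"]
    manifest: dict[str, Any] = {
        "package": "brewtime",
        "version": __version__,
        "seed": seed,
        "parameters": {k: config[k] for k in ("filters", "clustering", "diffexp")},
        "stages": {},
        "artifacts": {},
    }
    timings: dict[str, float] = {}

    def _write(name: str, writer, *args) -> Path:
        path = outdir / name
        writer(*args, path)
        manifest["artifacts"][name] = _sha256(path)
        return path

    def _stage(name: str, **info) -> None:
        manifest["stages"][name] = info
        logger.info("stage %-12s %s (%.2fs)", name, info, timings.get(name, 0.0))

    # ------------------------------------------------------------------ input
    t0 = time.perf_counter()
    truth = None
    unique_peptides = None
    if "simulate" in config:
        sim_cfg = simulation_config_from_dict(config["simulate"] or {}, seed)
        matrix, metadata, truth = simulate_timecourse(sim_cfg)
        bio.write_intensity_table(matrix, outdir / "intensity_raw.tsv")
        manifest["artifacts"]["intensity_raw.tsv"] = _sha256(outdir / "intensity_raw.tsv")
        _write("metadata.tsv", bio.write_metadata, metadata)
        (outdir / "ground_truth.json").write_text(
            json.dumps(
                {
                    "trajectory_class": truth.trajectory_class,
                    "batch_shifted": truth.batch_shifted,
                    "complexes": truth.complexes,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        manifest["artifacts"]["ground_truth.json"] = _sha256(outdir / "ground_truth.json")
    else:
        inputs = config.get("inputs", {})
        if "intensity" not in inputs or "metadata" not in inputs:
            raise ConfigurationError("config needs a 'simulate' block or inputs.intensity/metadata")
        matrix = bio.read_intensity_table(
            inputs["intensity"], dialect=inputs.get("dialect", "generic")
        )
        metadata = bio.read_metadata(inputs["metadata"])
        unique_peptides = getattr(matrix, "unique_peptides", None)
        if "psm" in inputs:
            psm = bio.read_psm_table(inputs["psm"])
            unique_peptides = psm.unique_peptides
    timings["input"] = time.perf_counter() - t0
    _stage("input", n_proteins=int(matrix.data.shape[0]), n_samples=int(matrix.data.shape[1]),
           n_measurements=matrix.n_measurements())

    # --------------------------------------------------------------- quantify
    t0 = time.perf_counter()
    filtered = qt.detection_filter(
        matrix, metadata, unique_peptides, min_unique_peptides=filters["min_unique_peptides"]
    ) if unique_peptides is not None else qt.detection_filter(matrix, metadata)
    centered = qt.log2_median_center(filtered)
    summed = qt.sum_replicates(matrix, metadata)
    rmn = qt.row_mean_normalize(summed)
    _write("intensity_log2_centered.tsv", bio.write_intensity_table, centered)
    _write("intensity_replicate_summed.tsv", bio.write_intensity_table, summed)
    _write("intensity_row_mean_normalized.tsv", bio.write_intensity_table, rmn)
    timings["quantify"] = time.perf_counter() - t0
    _stage("quantify", n_after_detection_filter=int(filtered.data.shape[0]),
           n_time_points=int(summed.data.shape[1]))

    # --------------------------------------------------------------------- qc
    t0 = time.perf_counter()
    rep = qc.replicate_qc(matrix, metadata)
    rep_path = outdir / "replicate_qc.tsv"
    rep.to_csv(rep_path, sep="\t", index=False)
    manifest["artifacts"]["replicate_qc.tsv"] = _sha256(rep_path)
    scorr = qc.sample_correlation(qt.log2_median_center(matrix))
    scorr_path = outdir / "sample_correlation.tsv"
    scorr.values.to_csv(scorr_path, sep="\t", index_label="sample", na_rep="NaN")
    manifest["artifacts"]["sample_correlation.tsv"] = _sha256(scorr_path)
    timings["qc"] = time.perf_counter() - t0
    _stage("qc", n_time_points=len(rep), mean_replicate_r=float(np.round(rep["pearson_r"].mean(), 6)))

    # ---------------------------------------------------------------- diffexp
    t0 = time.perf_counter()
    deps = de.dep_count_matrix(
        centered, metadata, fdr=filters["fdr"], min_log2fc=filters["min_log2fc"]
    )
    deps_path = outdir / "dep_counts.tsv"
    deps.to_csv(deps_path, sep="\t", index_label="time_point")
    manifest["artifacts"]["dep_counts.tsv"] = _sha256(deps_path)
    timings["diffexp"] = time.perf_counter() - t0
    iu = np.triu_indices(deps.shape[0], k=1)
    offdiag = deps.to_numpy()[iu]
    _stage("diffexp", n_pairs=int(offdiag.size), dep_min=int(offdiag.min()),
           dep_max=int(offdiag.max()), dep_mean=float(np.round(offdiag.mean(), 3)))

    # ---------------------------------------------------------------- cluster
    t0 = time.perf_counter()
    ccfg = config["clustering"]
    changed = cl.twofold_filter(rmn, min_abs_log2=filters["twofold"])
    if changed.data.shape[0] >= 2:
        tree = cl.hcluster(changed, metric=ccfg["metric"], method=ccfg["linkage"])
        assignment = cl.cut_by_node_depth(
            tree, ccfg["depth"], subset_threshold=ccfg["subset_threshold"],
            subset_depth=ccfg["subset_depth"],
        )
        clusters_path = outdir / "clusters.tsv"
        assignment.labels.rename("cluster").to_csv(clusters_path, sep="\t", index_label="protein_id")
        manifest["artifacts"]["clusters.tsv"] = _sha256(clusters_path)
        newick_path = outdir / "dendrogram.nwk"
        newick_path.write_text(bio.dendrogram_to_newick(tree) + "\n")
        manifest["artifacts"]["dendrogram.nwk"] = _sha256(newick_path)
        annotations = None
        ann_cfg = config.get("annotations", {})
        if "terms" in ann_cfg:
            annotations = bio.read_gmt(ann_cfg["terms"])
        elif truth is not None:
            annotations = {
                f"class:{name}": {p for p, c in truth.trajectory_class.items() if c == name}
                for name in set(truth.trajectory_class.values())
            }
        if annotations:
            universe = set(matrix.proteins)
            enrichment = cl.annotate_clusters(assignment, annotations, universe,
                                              fdr=filters["fdr"])
            enr_path = outdir / "cluster_enrichment.tsv"
            enrichment.to_csv(enr_path, sep="\t", index=False)
            manifest["artifacts"]["cluster_enrichment.tsv"] = _sha256(enr_path)
        timings["cluster"] = time.perf_counter() - t0
        _stage("cluster", n_filtered=int(changed.data.shape[0]),
               n_clusters=int(assignment.labels.nunique()))
    else:
        timings["cluster"] = time.perf_counter() - t0
        _stage("cluster", skipped="fewer than 2 proteins pass the two-fold filter")

    # ---------------------------------------------------------------- pathway
    t0 = time.perf_counter()
    ann_cfg = config.get("annotations", {})
    if "pathway_model" in ann_cfg:
        model = bio.read_pathway_model(ann_cfg["pathway_model"])
        ranking = pw.rank_pathways(model, rmn, top_n=config.get("pathway_top_n", 100))
        rank_path = outdir / "pathway_ranking.tsv"
        ranking.to_csv(rank_path, sep="\t", index=False)
        manifest["artifacts"]["pathway_ranking.tsv"] = _sha256(rank_path)
        removed = set(config.get("pathway_remove", []))
        if removed:
            shift = pw.leave_out_rerank(model, rmn, removed)
            shift_path = outdir / "pathway_rank_shift.tsv"
            shift.to_csv(shift_path, sep="\t", index=False)
            manifest["artifacts"]["pathway_rank_shift.tsv"] = _sha256(shift_path)
        timings["pathway"] = time.perf_counter() - t0
        _stage("pathway", n_pathways=len(model))
    else:
        timings["pathway"] = time.perf_counter() - t0
        _stage("pathway", skipped="no pathway model configured")

    # ------------------------------------------------------------ coregulation
    t0 = time.perf_counter()
    catalog: ComplexCatalog | None = None
    if "complexes" in ann_cfg:
        catalog = bio.read_complex_catalog(ann_cfg["complexes"])
    elif truth is not None and truth.complexes:
        catalog = ComplexCatalog({cid: set(m) for cid, m in truth.complexes.items()})
    if catalog is not None:
        pcorr = qc.protein_correlation(rmn)
        coverage, summary = cr.complex_coverage(catalog, set(matrix.proteins))
        cov_path = outdir / "complex_coverage.tsv"
        coverage.to_csv(cov_path, sep="\t", index=False)
        manifest["artifacts"]["complex_coverage.tsv"] = _sha256(cov_path)
        inter, non = cr.pair_correlation_split(pcorr, catalog)
        pairs_path = outdir / "pair_correlations.tsv"
        cr.pair_table(pcorr, catalog).to_csv(pairs_path, sep="\t", index=False)
        manifest["artifacts"]["pair_correlations.tsv"] = _sha256(pairs_path)
        coreg_summary = {
            "interacting_n": inter.count,
            "interacting_median_r": round(inter.median, 6),
            "non_interacting_n": non.count,
            "non_interacting_median_r": round(non.median, 6),
            "rank_sum_p": float(inter.p_value),
            **{k: round(v, 6) if isinstance(v, float) else v for k, v in summary.items()},
        }
        if "localization" in ann_cfg:
            locmap = bio.read_localization(ann_cfg["localization"])
            comps = cr.compartment_correlation(pcorr, locmap)
            comp_rows = [
                {"compartment": c, "n_pairs": s.count, "median_r": s.median, "mean_r": s.mean}
                for c, s in comps.items()
            ]
            comp_path = outdir / "compartment_correlation.tsv"
            pd.DataFrame(comp_rows).to_csv(comp_path, sep="\t", index=False)
            manifest["artifacts"]["compartment_correlation.tsv"] = _sha256(comp_path)
        timings["coregulation"] = time.perf_counter() - t0
        _stage("coregulation", **coreg_summary)
    else:
        timings["coregulation"] = time.perf_counter() - t0
        _stage("coregulation", skipped="no complex catalog configured")

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete; timings: %s",
                {k: round(v, 2) for k, v in timings.items()})
    return manifest
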