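"""End-to-end pipeline: simulate -> QC -> CNVR -> matrix -> structure -> V_ST.

Each stage reads only files written by earlier stages (the pipeline is a DAG
of files) and every run writes a ``run_manifest.json`` recording inputs,
parameters, seed and package version.  Reruns with the same config and seed
are byte-identical for every deterministic stage, which is all of them — the
only randomness is the seeded simulation and the seeded bootstrap.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from cnvpop import __version__
from cnvpop.annotate import annotate_regions, annotation_to_frame, gene_content_summary
from cnvpop.cnvr import merge_calls_to_regions, summarize_regions
from cnvpop.compare import venn_partition
from cnvpop.io import (
    read_annotation,
    write_chrom_sizes,
    write_cnv_calls,
    write_manifest,
    write_regions_bed,
    write_signal_matrix,
    write_snp_map,
)
from cnvpop.matrix import build_matrix, filter_min_carriers, write_matrix
from cnvpop.qc import QcThresholds, apply_qc_filters, compute_qc_reports, reports_to_frame
from cnvpop.simulate import CnvTemplate, SimulationConfig, generate_cohort
from cnvpop.structure import bootstrap_support, pca, sample_distances, upgma_tree
from cnvpop.vst import scan_to_frame, vst_scan


class PipelineError(RuntimeError):
    pass


def config_to_simulation(config: Mapping[str, Any], seed: int) -> SimulationConfig:
    sim = dict(config.get("simulate") or {})
    if "populations" not in sim:
        raise PipelineError("config missing required key: simulate.populations")
    templates = [
        CnvTemplate(
            chrom=str(t["chrom"]), start=int(t["start"]), end=int(t["end"]),
            tcn=int(t["tcn"]), carrier_freq={str(k): float(v) for k, v in t["carrier_freq"].items()},
        )
        for t in sim.pop("templates", [])
    ]
    if "call_rate_range" in sim:
        sim["call_rate_range"] = tuple(sim["call_rate_range"])
    if "lrr_state_means" in sim:
        sim["lrr_state_means"] = {int(k): float(v) for k, v in sim["lrr_state_means"].items()}
    return SimulationConfig(templates=templates, seed=seed, **sim)


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path, seed: int | None = None) -> Path:
    """Execute every configured stage; returns the output directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0)) if seed is None else int(seed)

    # -- simulate -----------------------------------------------------------
    sim_config = config_to_simulation(config, seed)
    probes, signal, truth, manifest, chrom_sizes = generate_cohort(sim_config)
    write_snp_map(probes, out / "snp_map.tsv")
    write_signal_matrix(signal, out / "lrr.tsv")
    if signal.baf is not None:
        write_signal_matrix(signal, out / "baf.tsv", which="baf")
    write_cnv_calls(truth, out / "calls.tsv")
    write_manifest(manifest, out / "manifest.tsv")
    write_chrom_sizes(chrom_sizes, out / "chrom_sizes.tsv")

    # -- per-sample QC ------------------------------------------------------
    qc_cfg = dict(config.get("qc") or {})
    reports = compute_qc_reports(signal, robust_dlrs=qc_cfg.pop("dlrs_robust", False))
    kept, excluded = apply_qc_filters(reports, QcThresholds(**qc_cfg))
    reports_to_frame(reports).to_csv(out / "qc_report.tsv", sep="\t", index=False)
    calls = [c for c in truth if c.sample_id in set(kept)]
    kept_manifest = {s: manifest[s] for s in kept}

    # -- CNVR merging and summaries ----------------------------------------
    regions = merge_calls_to_regions(calls)
    if not regions:
        raise PipelineError("no CNV regions after QC; nothing to analyze")
    write_regions_bed(regions, out / "cnvr.bed", sidecar=out / "cnvr.tsv")
    tables = summarize_regions(regions, chrom_sizes)
    tables["by_state"].rename_axis("state").to_csv(out / "cnvr_by_state.tsv", sep="\t")
    tables["by_chrom"].to_csv(out / "cnvr_by_chrom.tsv", sep="\t", index=False)

    # -- per-population comparison -----------------------------------------
    pops = sorted(set(kept_manifest.values()))
    if 2 <= len(pops) <= 3:
        per_pop_regions = {
            pop: merge_calls_to_regions(
                [c for c in calls if kept_manifest[c.sample_id] == pop]
            )
            for pop in pops
        }
        report = venn_partition(per_pop_regions)
        venn_json = {
            "totals": report.totals,
            "unique": report.unique_counts,
            "all_shared": report.all_shared_counts,
            "pairwise_shared": {f"{a}|{b}": v for (a, b), v in report.pairwise_shared.items()},
            "pairwise_fraction": {f"{a}|{b}": v for (a, b), v in report.pairwise_fraction.items()},
            "shared_length_bp": {f"{a}|{b}": v for (a, b), v in report.shared_length_bp.items()},
        }
        (out / "compare.json").write_text(json.dumps(venn_json, indent=2, sort_keys=True))

    # -- CNV matrix ---------------------------------------------------------
    mat_cfg = dict(config.get("matrix") or {})
    encoding = mat_cfg.get("encoding", "copy_number")
    matrix = build_matrix(regions, calls, kept_manifest, encoding=encoding)
    filtered = filter_min_carriers(
        matrix,
        k=int(mat_cfg.get("min_carriers", 5)),
        per_population=bool(mat_cfg.get("per_population", True)),
        manifest=kept_manifest,
    )
    write_matrix(filtered, out / "matrix.tsv")
    if not filtered.regions:
        raise PipelineError("no regions survive the carrier filter; lower min_carriers")

    # -- structure: PCA and UPGMA tree with bootstrap -----------------------
    pca_result = pca(filtered)
    coords = pd.DataFrame(
        pca_result.coordinates[:, :10],
        index=pca_result.sample_ids,
        columns=[f"PC{i + 1}" for i in range(min(10, pca_result.coordinates.shape[1]))],
    )
    coords.insert(0, "population", [kept_manifest[s] for s in pca_result.sample_ids])
    coords.rename_axis("sample_id").to_csv(out / "pca_coordinates.tsv", sep="\t")
    pd.DataFrame(
        {"component": [f"PC{i + 1}" for i in range(len(pca_result.variance_explained))],
         "variance_explained": pca_result.variance_explained}
    ).to_csv(out / "pca_variance.tsv", sep="\t", index=False)

    tree_cfg = dict(config.get("tree") or {})
    n_boot = int(tree_cfg.get("bootstrap", 100))
    metric = tree_cfg.get("metric", "euclidean")
    tree = bootstrap_support(filtered, n_boot=n_boot, seed=seed + 1, metric=metric)
    (out / "tree.nwk").write_text(tree.to_newick(with_support=True) + "\n")

    # -- V_ST scan ----------------------------------------------------------
    vst_cfg = dict(config.get("vst") or {})
    pairs = [tuple(p) for p in vst_cfg.get("pairs", [])]
    if not pairs and len(pops) >= 2:
        pairs = [(a, b) for i, a in enumerate(pops) for b in pops[i + 1:]]
    if pairs:
        scan_matrix = build_matrix(regions, calls, kept_manifest, encoding="presence")
        results = vst_scan(
            scan_matrix.regions, signal, kept_manifest, pairs,
            threshold_rule=vst_cfg.get("rule", "mean2sd"),
            min_carriers=int(vst_cfg.get("min_carriers", 5)),
            carrier_counts=scan_matrix.carrier_counts(kept_manifest),
        )
        scan_to_frame(results).to_csv(out / "vst_scan.tsv", sep="\t", index=False)

    # -- annotation (optional tracks) ---------------------------------------
    ann_cfg = dict(config.get("annotate") or {})
    track = []
    for key in ("genes", "qtl"):
        if ann_cfg.get(key):
            track.extend(read_annotation(ann_cfg[key]))
    if track:
        annotated = annotate_regions(regions, track)
        annotation_to_frame(regions, annotated).to_csv(out / "annotation.tsv", sep="\t", index=False)
        n_with, frac_with, n_without, frac_without = gene_content_summary(annotated)
        (out / "gene_content.json").write_text(
            json.dumps(
                {"n_with_genes": n_with, "fraction_with_genes": frac_with,
                 "n_without_genes": n_without, "fraction_without_genes": frac_without},
                indent=2, sort_keys=True,
            )
        )

    run_manifest = {
        "package": "cnvpop",
        "version": __version__,
        "seed": seed,
        "config": _jsonable(config),
        "n_samples_simulated": len(manifest),
        "n_samples_kept": len(kept),
        "n_samples_excluded": len(excluded),
        "n_truth_calls": len(truth),
        "n_regions": len(regions),
        "n_regions_filtered_matrix": len(filtered.regions),
    }
    (out / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2, sort_keys=True))
    return out


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
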