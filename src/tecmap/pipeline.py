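"""End-to-end orchestration and the run manifest.

A run is driven by a single YAML file with three blocks: ``params``
(mirroring :class:`~tecmap.datatypes.PipelineConfig`), either ``simulate``
(synthetic inputs) or ``inputs`` (paths to counts/TPM, lengths, sample
sheet, gene annotation), and optional ``compare`` (second-species calls +
ortholog table).  Every run writes a ``manifest.json`` capturing the
config snapshot, input digests, per-stage dimensions and timings, the
seed, and the tool version; re-running with the same manifest inputs and
seed reproduces the outputs exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as tio
from .classify import calls_from_tsv_frame, calls_to_tsv_frame, classify_all, elevated_counts_per_tissue
from .cluster import run_tissue_expression_clustering
from .cross_species import agreement_rate, classification_overlap, filter_orthologs, tissue_spearman
from .datatypes import PipelineConfig, Stage
from .enrichment import gene_set_enrichment
from .network import apply_display_rules, build_network, export_network
from .normalize import normalize_ladder
from .similarity import spearman_matrix, tissue_tree
from .synthetic import SyntheticConfig, generate

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_all(config_path, output_dir=None) -> dict:
    """Run simulate? -> normalize -> classify -> tree -> cluster -> enrich ->
    network -> compare?; returns the manifest dict."""
    config_path = Path(config_path)
    with open(config_path) as fh:
        run_cfg = yaml.safe_load(fh) or {}
    params = PipelineConfig.from_dict(run_cfg.get("params", {}))
    seed = int(run_cfg.get("seed", params.random_seed))
    out = Path(output_dir or run_cfg.get("output_dir", "tecmap_out"))
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "tool": "tecmap",
        "version": __version__,
        "seed": seed,
        "config_snapshot": run_cfg,
        "params": params.to_dict(),
        "inputs": {},
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    current_stage = "setup"

    def stage(name: str):
        nonlocal current_stage
        current_stage = name
        return time.monotonic()

    def done(name: str, t0: float, **dims) -> None:
        elapsed = time.monotonic() - t0
        manifest["stages"][name] = {**dims, "elapsed_s": round(elapsed, 3)}
        logger.info("stage %s done in %.2fs: %s", name, elapsed, dims)

    try:
        t0 = stage("inputs")
        if run_cfg.get("simulate", {}).get("enabled", False):
            sim = {k: v for k, v in run_cfg["simulate"].items() if k != "enabled"}
            ds = generate(SyntheticConfig(**sim), seed)
            counts, sheet, annotation, lengths = ds.counts, ds.sheet, ds.annotation, ds.lengths_kb
            tio.write_expression(counts, out / "counts.tsv")
            tio.write_gene_lengths(lengths, out / "gene_lengths.tsv")
            tio.write_sample_sheet(sheet, out / "samples.tsv")
            tio.write_gene_annotation(annotation, out / "gene_annotation.tsv")
            truth = ds.truth.copy()
            truth["elevated_tissues"] = truth["elevated_tissues"].map(";".join)
            tio.write_table(truth, out / "truth.tsv")
            stage_in = Stage.counts
        else:
            inputs = run_cfg.get("inputs")
            if not inputs:
                raise ValueError("config needs either simulate.enabled=true or an inputs block")
            for key in ("expression", "samples", "annotation"):
                if key not in inputs:
                    raise ValueError(f"inputs block missing field {key!r}")
                if not Path(inputs[key]).exists():
                    raise FileNotFoundError(f"inputs.{key}: no such file {inputs[key]!r}")
            stage_in = Stage(inputs.get("stage", "counts"))
            lengths = (
                tio.read_gene_lengths(inputs["lengths"]) if inputs.get("lengths") else None
            )
            counts = tio.read_expression(inputs["expression"], stage_in)
            sheet = tio.read_sample_sheet(inputs["samples"])
            annotation = tio.read_gene_annotation(inputs["annotation"])
            for key, path in inputs.items():
                if key != "stage" and path:
                    manifest["inputs"][key] = _sha256(Path(path))
        done("inputs", t0, genes=counts.shape[0], samples=counts.shape[1])

        t0 = stage("normalize")
        ladder = normalize_ladder(counts, sheet, annotation, lengths, stage_in=stage_in)
        nx_grouped = ladder["nx_grouped"]
        tio.write_expression(ladder["nx"], out / "nx_tissues.tsv")
        tio.write_expression(nx_grouped, out / "nx_grouped.tsv")
        tio.write_expression(ladder["sample_tmm"], out / "tmm_samples.tsv")
        tio.write_table(
            ladder["tmm_factors"].factors.rename("tmm_factor").rename_axis("column_id").reset_index(),
            out / "tmm_factors.tsv",
        )
        done("normalize", t0, genes=nx_grouped.shape[0], grouped_tissues=nx_grouped.shape[1])

        t0 = stage("classify")
        spec, dist = classify_all(nx_grouped, params)
        tio.write_table(calls_to_tsv_frame(spec, dist), out / "classification.tsv")
        tio.write_table(
            elevated_counts_per_tissue(spec).rename("n_elevated").rename_axis("tissue").reset_index(),
            out / "elevated_counts.tsv",
        )
        done("classify", t0, genes=len(spec))

        t0 = stage("tree")
        corr = spearman_matrix(ladder["nx"])
        tio.write_table(corr.reset_index(names="tissue"), out / "tissue_spearman.tsv")
        for method in ("ward", "average"):
            tissue_tree(corr, method).to_newick(out / f"tissue_tree_{method}.nwk")
        done("tree", t0, tissues=corr.shape[0])

        t0 = stage("cluster")
        emb, assignment = run_tissue_expression_clustering(
            ladder["sample_tmm"], spec, params, seed=seed
        )
        tio.write_table(assignment.to_gene_frame(emb), out / "clusters_genes.tsv")
        summary = assignment.clusters.copy()
        summary["significant_tissues"] = summary["significant_tissues"].map(";".join)
        tio.write_table(summary, out / "clusters_summary.tsv")
        tio.write_table(assignment.enrichment, out / "cluster_enrichment.tsv")
        done("cluster", t0, genes=len(assignment.labels), clusters=assignment.n_clusters)

        gmt_path = run_cfg.get("gene_sets")
        if gmt_path:
            t0 = stage("gene_sets")
            sets = tio.read_gmt(gmt_path)
            manifest["inputs"]["gene_sets"] = _sha256(Path(gmt_path))
            table = gene_set_enrichment(assignment.label_series, sets, params)
            tio.write_table(table, out / "gene_set_enrichment.tsv")
            done("gene_sets", t0, sets=len(sets), tests=len(table))

        t0 = stage("network")
        net = apply_display_rules(build_network(spec, sheet.organ_system_of()))
        export_network(net, out / "network.graphml", "graphml")
        export_network(net, out / "network.tsv", "tsv")
        done("network", t0, gene_nodes=len(net.gene_nodes), tissues=len(net.tissues))

        cmp_cfg = run_cfg.get("compare", {})
        if cmp_cfg.get("enabled", False):
            t0 = stage("compare")
            orthologs = filter_orthologs(tio.read_table(cmp_cfg["orthologs"]))
            calls_b = calls_from_tsv_frame(tio.read_table(cmp_cfg["calls_b"]))
            tissue_map = None
            if cmp_cfg.get("tissue_map"):
                tm = tio.read_table(cmp_cfg["tissue_map"])
                tissue_map = dict(zip(tm.iloc[:, 0].astype(str), tm.iloc[:, 1].astype(str)))
            overlap, contingency = classification_overlap(spec, calls_b, orthologs, tissue_map)
            flat = overlap.copy()
            for col in ("elevated_tissues_a", "elevated_tissues_b"):
                flat[col] = flat[col].map(";".join)
            tio.write_table(flat, out / "ortholog_overlap.tsv")
            tio.write_table(contingency.reset_index(names="category_a"), out / "ortholog_contingency.tsv")
            done(
                "compare", t0,
                pairs=len(overlap),
                agreement=round(agreement_rate(overlap), 4) if len(overlap) else None,
            )

        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        return manifest
    except Exception as exc:
        manifest["failed_stage"] = current_stage
        manifest["error"] = str(exc)
        with open(out / "manifest.partial.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise StageError(current_stage, exc) from exc
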