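"""Pipeline orchestration: simulate -> qc -> cluster -> markers -> annotate -> trajectory.

``run_all`` executes the six stages on a single YAML-compatible
configuration, writes every intermediate as TSV / 10X-layout text under
the output directory, and records a machine-readable run manifest
(config hash, per-stage inputs, outputs and seeds).  With the PCA
trajectory embedding the whole run is deterministic: rerunning with the
same config and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import annotate_clusters, build_overlap_table
from .core_io import (
    MarkerReference,
    read_marker_sets,
    write_10x_mtx,
    write_gene_list,
    write_marker_sets,
)
from .embed_cluster import cluster_cells, find_markers, lognormalize, pca_embed
from .qc import derive_induced_genes, filter_matrix
from .simulate import SimConfig, simulate_atlas, simulate_bulk_pair
from .trajectory import branch_features, infer_trajectory, subset_lineage

log = logging.getLogger("exoatlas")


class PipelineConfigError(ValueError):
    """The run configuration violates the schema."""


DEFAULT_CONFIG = {
    "simulate": {},  # SimConfig overrides
    "qc": {"lfc_min": 2.0, "alpha": 0.05, "min_cells": 4, "min_umi": 500,
           "max_organellar_frac": 0.01, "n_reps": 4},
    "cluster": {"n_pcs": 50, "n_use": 35, "k_neighbors": 20, "resolution": 1.0},
    "markers": {"min_pct": 0.1, "lfc_min": 0.25, "alpha": 0.05},
    "annotate": {"alpha": 0.01, "max_rank": 3, "variant": "standard"},
    "trajectory": {"embedding": "pca", "embed_dim": 10, "k_neighbors": 20,
                   "resolution": 0.8, "q_tip": 0.2},
}


@dataclass
class RunManifest:
    """Record of a pipeline run: config hash, stages, outputs, seeds."""

    config_hash: str
    seed: int
    version: str
    stages: list = field(default_factory=list)

    def add_stage(self, name, inputs, outputs, seed) -> None:
        self.stages.append(
            {
                "order": len(self.stages) + 1,
                "name": name,
                "inputs": [str(p) for p in inputs],
                "outputs": [str(p) for p in outputs],
                "seed": seed,
            }
        )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


def config_hash(config: dict) -> str:
    """SHA-256 of the canonical JSON form (stable under key reordering)."""
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    for key, val in user.items():
        if key == "reference_markers":
            continue
        if key not in cfg:
            raise PipelineConfigError(f"unknown config key: {key}")
        if not isinstance(val, dict):
            raise PipelineConfigError(f"config key {key} must be a mapping")
        allowed = (
            set(SimConfig.__dataclass_fields__) if key == "simulate" else set(cfg[key])
        )
        unknown = set(val) - allowed
        if unknown:
            raise PipelineConfigError(
                f"unknown config key: {key}.{sorted(unknown)[0]}"
            )
        cfg[key].update(val)
    if user.get("reference_markers") in (None, ""):
        raise PipelineConfigError("missing config key: reference_markers")
    cfg["reference_markers"] = user["reference_markers"]
    return cfg


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_all(config, out_dir, seed: int = 0) -> RunManifest:
    """Run the full synthetic pipeline; returns the manifest.

    Any stage failure aborts the run; the manifest written so far is
    preserved under ``out_dir/manifest.json``.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config_hash(cfg), seed=seed, version=__version__)
    manifest_path = out / "manifest.json"
    t0 = time.time()

    def stage_done(name, inputs, outputs, stage_seed=seed):
        log.info("[%s] done (%.1fs)", name, time.time() - t0)
        manifest.add_stage(name, inputs, outputs, stage_seed)
        manifest.write(manifest_path)

    try:
        # 1. simulate ----------------------------------------------------
        sim_cfg = SimConfig(**{**cfg["simulate"], "seed": seed})
        cm, truth = simulate_atlas(sim_cfg)
        bulk, design = simulate_bulk_pair(sim_cfg, n_reps=int(cfg["qc"]["n_reps"]))
        raw_dir = out / "raw"
        write_10x_mtx(cm, raw_dir)
        truth.cell_table(cm.barcodes).to_csv(out / "cell_truth.tsv", sep="\t", index=False)
        truth.gene_table().to_csv(out / "gene_truth.tsv", sep="\t", index=False)
        bulk.to_csv(out / "bulk.tsv", sep="\t")
        (out / "bulk_design.tsv").write_text(
            "".join(f"{n}\t{c}\n" for n, c in zip(bulk.columns, design))
        )
        stage_done("simulate", [], [raw_dir, out / "cell_truth.tsv",
                                    out / "gene_truth.tsv", out / "bulk.tsv"])

        # 2. qc ----------------------------------------------------------
        qc_cfg = cfg["qc"]
        induced = derive_induced_genes(
            bulk, design, lfc_min=qc_cfg["lfc_min"], alpha=qc_cfg["alpha"]
        )
        write_gene_list(induced, out / "induced.txt")
        filt, report = filter_matrix(
            cm,
            induced,
            min_cells=qc_cfg["min_cells"],
            min_umi=qc_cfg["min_umi"],
            max_organellar_frac=qc_cfg["max_organellar_frac"],
        )
        filt_dir = out / "filtered"
        write_10x_mtx(filt, filt_dir)
        report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
        stage_done("qc", [raw_dir, out / "bulk.tsv"],
                   [out / "induced.txt", filt_dir, out / "qc_report.tsv"])

        # 3. cluster -----------------------------------------------------
        cl = cfg["cluster"]
        x = lognormalize(filt)
        emb = pca_embed(x, n_pcs=cl["n_pcs"])
        labels = cluster_cells(
            emb, n_use=cl["n_use"], k_neighbors=cl["k_neighbors"],
            resolution=cl["resolution"], seed=seed,
        )
        _write_tsv(
            pd.DataFrame({"barcode": filt.barcodes, "cluster": labels.labels}),
            out / "labels.tsv",
        )
        stage_done("cluster", [filt_dir], [out / "labels.tsv"])

        # 4. markers -----------------------------------------------------
        mk = cfg["markers"]
        markers = find_markers(
            x, labels, genes=filt.genes,
            min_pct=mk["min_pct"], lfc_min=mk["lfc_min"], alpha=mk["alpha"],
        )
        _write_tsv(markers.table, out / "markers.tsv")
        stage_done("markers", [out / "labels.tsv"], [out / "markers.tsv"])

        # 5. annotate ----------------------------------------------------
        an = cfg["annotate"]
        if cfg["reference_markers"] == "truth":
            ref = MarkerReference({t: set(s) for t, s in truth.marker_sets.items()})
            write_marker_sets(ref, out / "reference_markers.tsv")
        else:
            ref = read_marker_sets(cfg["reference_markers"])
        overlap = build_overlap_table(markers, ref)
        ann = annotate_clusters(
            overlap, alpha=an["alpha"], max_rank=an["max_rank"], variant=an["variant"]
        )
        _write_tsv(ann.to_frame(), out / "annotation.tsv")
        _write_tsv(
            pd.DataFrame(
                sorted(ann.primary_labels.items()), columns=["cluster", "primary"]
            ),
            out / "primary_labels.tsv",
        )
        stage_done("annotate", [out / "markers.tsv"],
                   [out / "annotation.tsv", out / "primary_labels.tsv"])

        # 6. trajectory --------------------------------------------------
        tj = cfg["trajectory"]
        primary = ann.primary_labels
        lineage_types = set(sim_cfg.types)
        selected = [c for c in sorted(primary) if primary[c] in lineage_types]
        if not selected:
            raise PipelineConfigError("no cluster annotated with a lineage type")
        xs, sub_idx = subset_lineage(x, labels, selected)
        cell_primary = np.array(
            [primary[c] for c in labels.labels[sub_idx]], dtype=object
        )
        root_mask = np.isin(cell_primary, list(sim_cfg.anchor_types))
        graph, assign, ms_labels = infer_trajectory(
            xs, root_mask,
            embed_dim=tj["embed_dim"], k_neighbors=tj["k_neighbors"],
            resolution=tj["resolution"], seed=seed, embedding=tj["embedding"],
        )
        _write_tsv(
            pd.DataFrame(
                [(u, v, w) for u, v, w in graph.edges],
                columns=["milestone_a", "milestone_b", "length"],
            ),
            out / "tree.tsv",
        )
        _write_tsv(
            pd.DataFrame(
                {
                    "barcode": filt.barcodes[sub_idx],
                    "milestone": ms_labels.labels,
                    "edge_a": [e[0] for e in assign.edge],
                    "edge_b": [e[1] for e in assign.edge],
                    "pseudotime": assign.pseudotime,
                    "branch": assign.branch,
                }
            ),
            out / "pseudotime.tsv",
        )
        feats = branch_features(
            xs, assign, graph, genes=filt.genes, q=tj["q_tip"],
            milestone_labels=ms_labels,
        )
        long = (
            feats.tip_restriction.rename_axis("gene")
            .reset_index()
            .melt(id_vars="gene", var_name="branch", value_name="tip_restriction")
        )
        corr_long = (
            feats.correlation.rename_axis("gene")
            .reset_index()
            .melt(id_vars="gene", var_name="branch", value_name="correlation")
        )
        merged = long.merge(corr_long, on=["gene", "branch"])
        _write_tsv(merged, out / "branch_features.tsv")
        stage_done("trajectory", [out / "labels.tsv"],
                   [out / "tree.tsv", out / "pseudotime.tsv", out / "branch_features.tsv"])
    except Exception:
        manifest.write(manifest_path)
        raise
    return manifest
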