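"""End-to-end pipeline driver: simulate -> qc -> cluster -> map ->
markers / diversity / pseudocell-ARG / saturation, with a machine-readable
summary and a resolved-config snapshot written alongside every run."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as atlas_io
from .clustering import iterative_cluster
from .config import PipelineConfig, STAGES
from .diversity import confident_type_counts, region_similarity, types_for_coverage
from .mapping import build_region_reference, map_beads
from .pseudocell import (arg_candidates, arg_clusters, arg_network,
                         build_pseudocells, normalize_pseudocells)
from .qc import GeneFamilies, basic_filter, quality_metrics, quality_network_qc
from .saturation import (SaturationSpec, required_count_for_fraction,
                         success_probability)
from .setcover import marker_covers
from .synthetic import build_ground_truth, simulate_beads, simulate_cells

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]

DEPENDENCIES = {
    "qc": ["simulate"],
    "cluster": ["qc"],
    "map": ["cluster"],
    "markers": ["cluster"],
    "diversity": ["map"],
    "pseudocell": ["cluster"],
    "arg": ["pseudocell"],
}


def _check_stage_order(stages):
    enabled = set(stages)
    for stage in stages:
        for dep in DEPENDENCIES.get(stage, []):
            if dep not in enabled:
                raise ValueError(f"stage {stage!r} requires {dep!r} to be enabled")


def _nonzero_fraction_table(cells, labels) -> pd.DataFrame:
    labs = np.asarray(labels, dtype=object)
    types = sorted({l for l in labs if l not in ("", None)})
    rows = []
    for t in types:
        sub = cells.counts[np.flatnonzero(labs == t)]
        rows.append(np.asarray((sub > 0).mean(axis=0)).ravel())
    return pd.DataFrame(rows, index=types, columns=cells.gene_ids)


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute the enabled stages in dependency order; returns the run
    directory containing per-stage outputs, ``summary.json`` and the
    resolved-config snapshot."""
    cfg = config
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGES if s in set(cfg.stages)]
    _check_stage_order(stages)
    (out / "config.json").write_text(
        json.dumps({"hash": cfg.config_hash(), "resolved": cfg.resolved()},
                   indent=2, sort_keys=True))
    summary: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
                     "stages": stages}
    t_start = time.time()

    cells = beads = truth = None
    tree = None
    labels = None
    mapping = None
    pseudocells = None

    if "simulate" in stages:
        truth = build_ground_truth(cfg.generator)
        cells = simulate_cells(truth, cfg.n_cells, cfg.cell_depth_median,
                               seed=cfg.seed + 1)
        beads = simulate_beads(truth, cfg.n_beads, cfg.bead_depth_median,
                               cfg.bead_doublet_fraction, seed=cfg.seed + 2)
        truth.to_json(out / "ground_truth.json")
        atlas_io.write_counts(cells, out / "cells")
        atlas_io.write_counts(beads, out / "beads")
        summary["n_cells_simulated"] = cells.n_cells
        summary["n_beads_simulated"] = beads.n_beads

    if "qc" in stages:
        report = basic_filter(cells, cfg.min_umis, cfg.max_mito)
        keep = np.isin(cells.cell_meta["cell_id"].values, report.retained)
        cells = cells.subset(keep)
        removed_frames = [report.removed]
        if cfg.run_quality_network:
            metrics = quality_metrics(cells)
            classes = np.full(cells.n_cells, "neuron", dtype=object)
            net_report = quality_network_qc(cells, metrics, classes,
                                            seed=cfg.seed + 3)
            keep = np.isin(cells.cell_meta["cell_id"].values,
                           net_report.retained)
            cells = cells.subset(keep)
            removed_frames.append(net_report.removed)
        removed = pd.concat(removed_frames, ignore_index=True)
        removed.to_csv(out / "qc_removed.csv", index=False)
        summary["n_cells_after_qc"] = cells.n_cells
        summary["n_cells_removed"] = int(len(removed))

    if "cluster" in stages:
        ccfg = dataclasses.replace(cfg.clustering, seed=cfg.seed + 4)
        tree = iterative_cluster(cells, ccfg)
        labels = tree.leaf_assignments(cells.n_cells)
        assign = pd.DataFrame({"cell_id": cells.cell_meta["cell_id"],
                               "leaf": labels})
        assign.to_csv(out / "leaf_assignments.csv", index=False)
        tree_payload = {
            "leaves": tree.leaves,
            "nodes": {k: {kk: vv for kk, vv in v.items() if kk != "members"}
                      | {"n_members": len(v["members"])}
                      for k, v in tree.nodes.items()},
            "n_discarded": int(tree.all_discarded().size),
        }
        (out / "cluster_tree.json").write_text(json.dumps(tree_payload, indent=1))
        summary["leaf_count"] = len(tree.leaves)
        summary["discard_fraction"] = round(
            tree.all_discarded().size / cells.n_cells, 6)

    if "map" in stages:
        references = {}
        for region in sorted(set(beads.bead_meta["region"])):
            try:
                references[region] = build_region_reference(
                    cells, labels, region, cfg.mapping)
            except ValueError as exc:
                logger.warning("region %s: %s", region, exc)
        mapping = map_beads(beads, references, cfg.mapping)
        mapping.beads.to_csv(out / "bead_mapping.csv", index=False)
        mapping.confidences.to_csv(out / "bead_confidences.csv", index=False)
        elig = mapping.beads["eligible"].fillna(False)
        summary["n_beads_eligible"] = int(elig.sum())
        summary["n_beads_confident"] = int(
            mapping.confidences[mapping.confidences["confident"]]
            ["bead_id"].nunique())

    if "markers" in stages:
        fractions = _nonzero_fraction_table(cells, labels)
        covers = marker_covers(fractions, cfg.tau_on, cfg.tau_off,
                               cfg.max_cover_size)
        rows = [{"type": t, "feasible": c.feasible, "size": c.size,
                 "genes": ";".join(c.genes)} for t, c in covers.items()]
        pd.DataFrame(rows).to_csv(out / "marker_covers.csv", index=False)
        sizes = [c.size for c in covers.values() if c.feasible]
        summary["marker_cover_sizes"] = {
            "median": float(np.median(sizes)) if sizes else None,
            "feasible": len(sizes), "infeasible": len(rows) - len(sizes),
        }

    if "diversity" in stages:
        if mapping.confidences.empty:
            raise RuntimeError("diversity stage: no confident bead mappings")
        counts = confident_type_counts(mapping)
        n95 = {r: types_for_coverage(counts.loc[r], cfg.coverage_q)
               for r in counts.index if counts.loc[r].sum() > 0}
        sim = region_similarity(weights=counts)
        counts.to_csv(out / "region_type_counts.csv")
        sim.to_csv(out / "region_similarity.tsv", sep="\t")
        summary["n95_per_region"] = n95

    if "pseudocell" in stages:
        # cell group = the leaf's ancestor one level below the root
        # (a metacluster stand-in)
        group_of = {}
        for leaf in tree.leaves:
            node = leaf
            while tree.nodes[node]["parent"] not in (None, "root"):
                node = tree.nodes[node]["parent"]
            group_of[leaf] = node
        pseudocells = build_pseudocells(cells, labels, groups=group_of,
                                        seed=cfg.seed + 5)
        normalize_pseudocells(pseudocells)
        pseudocells.meta.to_csv(out / "pseudocells.csv")
        summary["n_pseudocells"] = int(pseudocells.counts.shape[0])

    if "arg" in stages:
        anchor = truth.activity_spec["anchor"] if truth else "Fos"
        table = arg_candidates(pseudocells.normalized,
                               pseudocells.meta["cell_group"], anchor,
                               cfg.arg_r_min, cfg.arg_quantile, cfg.arg_alpha)
        table.to_csv(out / "arg_table.csv", index=False)
        cand = sorted(set(table.loc[table["candidate"], "gene"]))
        summary["n_arg_candidates"] = len(cand)
        if cand:
            net = arg_network(table, cfg.arg_prune, cfg.arg_core_degree)
            net.to_csv(out / "arg_network.csv", index=False)
            summary["n_core_iegs"] = int(net["core_ieg"].sum())
            if len(cand) >= cfg.arg_k_clusters:
                clusters = arg_clusters(table, cfg.arg_k_clusters)
                clusters.to_csv(out / "arg_clusters.csv")

    if "saturation" in stages:
        c = required_count_for_fraction(cfg.sat_n_rarest, cfg.sat_c_fraction)
        spec = SaturationSpec(k=cfg.sat_k, p_type=cfg.sat_n_rarest / cfg.sat_total,
                              c=c)
        summary["saturation"] = {
            "c": c,
            "rare_type_frequency_pct": round(
                100 * cfg.sat_n_rarest / cfg.sat_total, 6),
            "probability_at_n": round(success_probability(cfg.sat_at, spec), 6),
        }

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "run.log").write_text(
        f"stages={stages}\nruntime_s={round(time.time() - t_start, 1)}\n")
    return out
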