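"""Nucleus- and cluster-level quality control.

Hard filters (UMIs < 500 or mitochondrial fraction > 1% remove a nucleus),
doublet-cluster flagging by co-expression of markers of distinct cell
classes, and a multi-metric "quality network": per class (neuron / glia),
cells are embedded on eight standardized quality metrics, clustered with
SNN + Leiden (resolution 0.8), and a quality-cluster is removed when its
median exceeds the 85th percentile of the class in all three of the oxphos,
mitochondrial and ribosomal fractions, or when it has fewer than 15 cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd

from . import synthetic as syn
from .clustering import _knn_adjacency, snn_from_knn
from .synthetic import CellProfileMatrix

__all__ = [
    "GeneFamilies",
    "QcReport",
    "quality_metrics",
    "basic_filter",
    "flag_doublet_clusters",
    "quality_network_qc",
    "DEFAULT_DOUBLET_PAIRS",
]

METRICS = ["pct_oxphos", "pct_mito", "pct_ribo", "pct_ieg", "pct_top50",
           "pct_lncRNA", "log2_genes", "log2_umis"]
OUTLIER_METRICS = ["pct_oxphos", "pct_mito", "pct_ribo"]

# cross-class marker pairs for doublet-cluster flagging (oligodendrocyte /
# glutamatergic / GABAergic / astrocyte class markers)
DEFAULT_DOUBLET_PAIRS = [
    ("Mbp", "Slc17a7"),
    ("Mbp", "Gad1"),
    ("Slc17a7", "Gad1"),
    ("Aqp4", "Slc17a7"),
    ("Aqp4", "Mbp"),
]


@dataclass
class GeneFamilies:
    """Gene families for the QC metrics, resolved by id prefix or explicit
    list; defaults match the synthetic generator's naming scheme."""

    mito_prefixes: tuple = (syn.MITO_PREFIX,)
    ribo_prefixes: tuple = syn.RIBO_PREFIXES
    oxphos_prefixes: tuple = (syn.OXPHOS_PREFIX,)
    lnc_prefixes: tuple = (syn.LNC_PREFIX,)
    ieg_genes: tuple = tuple(syn.DEFAULT_IEGS)

    def indices(self, gene_ids, family: str) -> np.ndarray:
        if family == "ieg":
            sel = [i for i, g in enumerate(gene_ids) if g in set(self.ieg_genes)]
        else:
            prefixes = getattr(self, f"{family}_prefixes")
            sel = [i for i, g in enumerate(gene_ids) if g.startswith(tuple(prefixes))]
        return np.asarray(sel, dtype=int)


@dataclass
class QcReport:
    retained: list
    removed: pd.DataFrame  # columns: cell_id, reason
    cluster_medians: pd.DataFrame = field(default_factory=pd.DataFrame)

    REASONS = ("low_umi", "high_mito", "quality_cluster", "small_cluster",
               "doublet_cluster")

    def removed_ids(self) -> set:
        return set(self.removed["cell_id"])


def quality_metrics(cells: CellProfileMatrix,
                    families: GeneFamilies | None = None) -> pd.DataFrame:
    """The eight per-cell quality metrics (fractions of total counts, plus
    log2 gene and UMI numbers)."""
    fam = families or GeneFamilies()
    X = cells.counts
    depths = cells.depths().astype(float)
    if (depths <= 0).any():
        raise ValueError("cells with zero counts; run basic filtering upstream")
    out = {}
    for name, key in [("pct_oxphos", "oxphos"), ("pct_mito", "mito"),
                      ("pct_ribo", "ribo"), ("pct_ieg", "ieg"),
                      ("pct_lncRNA", "lnc")]:
        idx = fam.indices(cells.gene_ids, key)
        frac = (np.asarray(X[:, idx].sum(axis=1)).ravel() / depths
                if idx.size else np.zeros(X.shape[0]))
        out[name] = frac
    # fraction of counts in the cell's own 50 highest-expressed genes
    top50 = np.empty(X.shape[0])
    k = min(50, X.shape[1])
    for i in range(X.shape[0]):
        row = X.getrow(i).data
        if row.size <= k:
            top50[i] = 1.0
        else:
            top50[i] = np.sort(row)[-k:].sum() / depths[i]
    out["pct_top50"] = top50
    out["log2_genes"] = np.log2(np.asarray((X > 0).sum(axis=1)).ravel())
    out["log2_umis"] = np.log2(depths)
    return pd.DataFrame(out, index=cells.cell_meta["cell_id"].values)[METRICS]


def basic_filter(cells: CellProfileMatrix, min_umis: int = 500,
                 max_mito: float = 0.01,
                 families: GeneFamilies | None = None) -> QcReport:
    """Remove nuclei with fewer than ``min_umis`` total UMIs or a
    mitochondrial fraction strictly greater than ``max_mito``."""
    fam = families or GeneFamilies()
    mito_idx = fam.indices(cells.gene_ids, "mito")
    if mito_idx.size == 0:
        raise ValueError("mitochondrial gene family matches no genes")
    depths = cells.depths().astype(float)
    mito = np.asarray(cells.counts[:, mito_idx].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(depths > 0, mito / np.maximum(depths, 1), 1.0)
    low = depths < min_umis
    high = ~low & (mito_frac > max_mito)
    ids = cells.cell_meta["cell_id"].values
    removed = pd.DataFrame({
        "cell_id": np.concatenate([ids[low], ids[high]]),
        "reason": ["low_umi"] * int(low.sum()) + ["high_mito"] * int(high.sum()),
    })
    return QcReport(retained=ids[~(low | high)].tolist(), removed=removed)


def flag_doublet_clusters(clusters: np.ndarray, cells: CellProfileMatrix,
                          marker_pairs=None, tau_coexp: float = 0.5) -> set:
    """Flag clusters co-expressing both genes of a cross-class marker pair
    (each nonzero in >= ``tau_coexp`` of the cluster's cells)."""
    if marker_pairs is None:
        marker_pairs = DEFAULT_DOUBLET_PAIRS
    gi = {g: i for i, g in enumerate(cells.gene_ids)}
    unknown = sorted({g for p in marker_pairs for g in p if g not in gi})
    if unknown:
        raise ValueError(f"unknown genes in marker pairs: {unknown}")
    pairs = list(marker_pairs)
    flagged = set()
    labs = np.asarray(clusters)
    for cl in pd.unique(labs):
        mask = labs == cl
        sub = cells.counts[np.flatnonzero(mask)]
        for a, b in pairs:
            fa = (sub[:, gi[a]] > 0).sum() / mask.sum()
            fb = (sub[:, gi[b]] > 0).sum() / mask.sum()
            if fa >= tau_coexp and fb >= tau_coexp:
                flagged.add(cl)
                break
    return flagged


def quality_network_qc(cells: CellProfileMatrix, metrics: pd.DataFrame,
                       class_split: np.ndarray, k: int = 50,
                       resolution: float = 0.8, percentile: float = 85.0,
                       min_cluster: int = 15, seed: int = 0) -> QcReport:
    """Quality-network outlier removal, run separately per class.

    Within each class the eight metrics are z-scored, a k=50 Euclidean kNN ->
    Jaccard SNN graph is built and Leiden-clustered (modularity, resolution
    0.8). A quality-cluster is removed when its median exceeds the class's
    85th percentile in all of oxphos, mito and ribo fractions; remaining
    quality-clusters under 15 cells are also removed.
    """
    ids = cells.cell_meta["cell_id"].values
    classes = np.asarray(class_split)
    removed_rows = []
    medians_rows = []
    for cls in pd.unique(classes):
        mask = classes == cls
        n = int(mask.sum())
        if n < 30:
            warnings.warn(f"class {cls!r} has {n} cells; skipping network QC")
            continue
        M = metrics.loc[ids[mask], METRICS].values.astype(float)
        mu, sd = M.mean(axis=0), M.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (M - mu) / sd
        kk = min(k, n - 1)
        adj = _knn_adjacency(Z, kk, metric="euclidean")
        snn = snn_from_knn(adj, kk)
        g = ig.Graph(n=n, edges=list(zip(snn.row.tolist(), snn.col.tolist())),
                     edge_attrs={"weight": snn.data.tolist()})
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition, weights="weight",
            resolution_parameter=resolution, seed=seed, n_iterations=2)
        labels = np.asarray(part.membership)
        thresholds = {m: np.percentile(metrics.loc[ids[mask], m], percentile)
                      for m in OUTLIER_METRICS}
        cls_ids = ids[mask]
        outlier_clusters, kept = set(), []
        for cl in np.unique(labels):
            sel = labels == cl
            med = {m: float(np.median(metrics.loc[cls_ids[sel], m]))
                   for m in METRICS}
            medians_rows.append({"class": cls, "cluster": int(cl),
                                 "n_cells": int(sel.sum()), **med})
            if all(med[m] > thresholds[m] for m in OUTLIER_METRICS):
                outlier_clusters.add(cl)
                removed_rows.extend(
                    {"cell_id": c, "reason": "quality_cluster"} for c in cls_ids[sel])
            else:
                kept.append(cl)
        for cl in kept:
            sel = labels == cl
            if sel.sum() < min_cluster:
                removed_rows.extend(
                    {"cell_id": c, "reason": "small_cluster"} for c in cls_ids[sel])
    removed = pd.DataFrame(removed_rows, columns=["cell_id", "reason"])
    retained = [c for c in ids if c not in set(removed["cell_id"])]
    return QcReport(retained=retained, removed=removed,
                    cluster_medians=pd.DataFrame(medians_rows))
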