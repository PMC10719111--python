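"""Pseudocells and activity-regulated-gene (ARG) analysis.

Cells of a type are aggregated into pseudocells of target size
s = min(200, max(20, n/50)); centres come from k-means on variance-weighted
principal components and cells are attached by iterative majority label
propagation over the within-type kNN graph. Pseudocell counts are
normalized as log2 CPM -> quantile normalization -> per-gene z-score.

A gene is a candidate ARG in a cell group when its Pearson correlation with
the anchor IEG (Fos) is >= 0.3, sits in the top 0.5% of that gene's
correlations with all genes, and is Holm-significant (adjusted p < 0.05);
the final list is the union over groups. The gene x group incidence
(r + 1, edges under 1.3 pruned) gives a bipartite network whose high-degree
genes (> 18) are the core IEGs; ARG clusters come from Ward agglomeration
on the gene x group correlation profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster import hierarchy
from scipy.stats import fisher_exact, rankdata, t as t_dist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .clustering import _knn_adjacency
from .synthetic import CellProfileMatrix

__all__ = [
    "pseudocell_size",
    "PseudocellSet",
    "build_pseudocells",
    "normalize_pseudocells",
    "holm_adjust",
    "arg_candidates",
    "arg_network",
    "arg_clusters",
    "geneset_overlap",
]


def pseudocell_size(n: int) -> float:
    """Target pseudocell size for a type of n cells: min(200, max(20, n/50))."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return min(200.0, max(20.0, n / 50.0))


@dataclass
class PseudocellSet:
    counts: sp.csr_matrix  # pseudocells x genes, aggregated raw UMIs
    membership: pd.Series  # cell_id -> pseudocell id
    meta: pd.DataFrame  # pseudocell id, cell_type, cell_group, n_cells
    gene_ids: list[str]
    normalized: pd.DataFrame | None = None
    zero_variance_genes: list = field(default_factory=list)


def _assign_by_label_propagation(X: np.ndarray, init_labels: np.ndarray,
                                 k: int = 15, n_iter: int = 2) -> np.ndarray:
    """Majority label propagation over the within-type kNN graph, seeded from
    k-means labels (a random-walk-flavoured boundary smoothing).

    Only a couple of iterations are run: the goal is to reassign boundary
    cells toward their expression neighbourhood, not to recluster. If the
    smoothing empties a pseudocell (possible on a featureless type), the
    k-means labels are kept so the pseudocell count stays at round(n/s).
    """
    n = X.shape[0]
    kk = min(k, n - 1)
    if kk < 1:
        return init_labels
    adj = _knn_adjacency(X, kk, metric="euclidean")
    labels = init_labels.copy()
    n_labels = labels.max() + 1
    for _ in range(n_iter):
        onehot = sp.csr_matrix(
            (np.ones(n), (np.arange(n), labels)), shape=(n, n_labels))
        votes = (adj @ onehot).toarray() + onehot.toarray()  # self vote
        new = votes.argmax(axis=1)
        if (new == labels).all():
            break
        labels = new
    if np.unique(labels).size < n_labels:
        return init_labels
    return labels


def build_pseudocells(cells: CellProfileMatrix, leaf_assignments,
                      groups: dict | None = None, seed: int = 0,
                      n_components: int = 50) -> PseudocellSet:
    """Aggregate cells into pseudocells within each type.

    Per type: PCA on scaled sqrt counts, components weighted by variance
    explained, k-means with k = round(n/s) centres, then label propagation
    on the within-type kNN graph; raw UMIs are summed per pseudocell.
    ``groups`` optionally maps type -> cell group label for the ARG stage.
    """
    rng = np.random.RandomState(seed)
    labs = np.asarray(leaf_assignments, dtype=object)
    ids = cells.cell_meta["cell_id"].values
    membership = pd.Series(index=ids, dtype=object)
    rows, meta_rows = [], []
    pc_counter = 0
    for t in sorted({l for l in labs if l not in ("", None)}):
        members = np.flatnonzero(labs == t)
        n = members.size
        s = pseudocell_size(n)
        k = max(1, round(n / s))
        X = np.sqrt(cells.counts[members].toarray())
        if k == 1 or n < 2 * s:
            assign = np.zeros(n, dtype=int)
            k = 1
        else:
            mu, sd = X.mean(axis=0), X.std(axis=0)
            sd[sd == 0] = 1.0
            Z = (X - mu) / sd
            ncomp = int(min(n_components, n - 1, Z.shape[1]))
            pca = PCA(n_components=ncomp, random_state=rng.randint(2**31 - 1))
            pcs = pca.fit_transform(Z)
            pcs = pcs * pca.explained_variance_ratio_
            km = KMeans(n_clusters=k, random_state=rng.randint(2**31 - 1),
                        n_init=5)
            init = km.fit_predict(pcs)
            assign = _assign_by_label_propagation(pcs, init)
            # empty pseudocells after propagation are dropped by re-indexing
            uniq, assign = np.unique(assign, return_inverse=True)
            k = uniq.size
        for local in range(k):
            sel = members[assign == local]
            pc_id = f"pc{pc_counter:05d}"
            pc_counter += 1
            agg = np.asarray(cells.counts[sel].sum(axis=0)).ravel()
            rows.append(agg)
            membership.loc[ids[sel]] = pc_id
            meta_rows.append({
                "pseudocell": pc_id, "cell_type": t,
                "cell_group": (groups or {}).get(t, t), "n_cells": int(sel.size),
            })
    counts = sp.csr_matrix(np.vstack(rows).astype(np.int64))
    meta = pd.DataFrame(meta_rows).set_index("pseudocell")
    return PseudocellSet(counts=counts, membership=membership, meta=meta,
                         gene_ids=list(cells.gene_ids))


def quantile_normalize(mat: np.ndarray) -> np.ndarray:
    """Quantile normalization of rows-as-samples to the mean empirical
    distribution, ties shared by average rank."""
    n, g = mat.shape
    mean_sorted = np.sort(mat, axis=1).mean(axis=0)
    out = np.empty_like(mat, dtype=float)
    for i in range(n):
        ranks = rankdata(mat[i], method="average")  # 1..g, ties averaged
        out[i] = np.interp(ranks, np.arange(1, g + 1), mean_sorted)
    return out


def normalize_pseudocells(pcs: PseudocellSet) -> pd.DataFrame:
    """log2 CPM -> quantile normalization -> per-gene standardization.
    Zero-variance genes are flagged and left at zero rather than scaled."""
    if pcs.counts.shape[0] < 2:
        raise ValueError("need at least 2 pseudocells")
    totals = np.asarray(pcs.counts.sum(axis=1)).ravel().astype(float)
    if (totals == 0).any():
        raise ValueError("zero-count pseudocell (upstream bug)")
    cpm = pcs.counts.toarray() / totals[:, None] * 1e6
    logged = np.log2(cpm + 1.0)
    qn = quantile_normalize(logged)
    mu = qn.mean(axis=0)
    sd = qn.std(axis=0)
    zero_var = sd < 1e-12
    sd_safe = np.where(zero_var, 1.0, sd)
    z = (qn - mu) / sd_safe
    z[:, zero_var] = 0.0
    norm = pd.DataFrame(z, index=pcs.meta.index, columns=pcs.gene_ids)
    pcs.normalized = norm
    pcs.zero_variance_genes = [g for g, f in zip(pcs.gene_ids, zero_var) if f]
    return norm


def holm_adjust(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def _pearson_with_p(X: np.ndarray, y: np.ndarray):
    """Columnwise Pearson r of X against y, with two-sided t-transform p."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((Xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Xc.T @ yc / denom, 0.0)
    r = np.clip(r, -0.9999999999, 0.9999999999)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * t_dist.sf(np.abs(tstat), df=max(n - 2, 1))
    return r, p


def arg_candidates(normalized: pd.DataFrame, groups: pd.Series, anchor: str,
                   r_min: float = 0.3, quantile: float = 0.995,
                   alpha: float = 0.05, min_pseudocells: int = 10) -> pd.DataFrame:
    """Candidate ARGs per cell group and the union list.

    Per group, each gene's Pearson r with the anchor across the group's
    pseudocells; candidate iff r >= ``r_min``, r is in the top
    (1 - ``quantile``) of the gene's correlations with all genes in that
    group, and the Holm-adjusted (within group, across genes) two-sided p
    is < ``alpha``. The anchor is excluded from its own list.
    """
    if anchor not in normalized.columns:
        raise ValueError(f"anchor {anchor!r} not in the matrix")
    rows = []
    genes = [g for g in normalized.columns]
    groups = pd.Series(np.asarray(groups), index=normalized.index)
    for group in pd.unique(groups):
        sub = normalized.loc[groups[groups == group].index]
        if len(sub) < min_pseudocells:
            warnings.warn(f"group {group!r} has {len(sub)} pseudocells; skipped")
            continue
        y = sub[anchor].values
        if np.std(y) == 0:
            warnings.warn(f"anchor has zero variance in group {group!r}; skipped")
            continue
        X = sub.values
        r_anchor, p_anchor = _pearson_with_p(X, y)
        p_adj = holm_adjust(p_anchor)
        # per-gene quantile rank of the anchor correlation among the gene's
        # correlations with all genes (full correlation matrix per group)
        Z = (X - X.mean(axis=0))
        sd = np.sqrt((Z**2).sum(axis=0))
        sd[sd == 0] = np.inf
        U = Z / sd
        C = U.T @ U  # gene x gene Pearson correlations
        np.fill_diagonal(C, -np.inf)  # self-correlation never counted
        ranks = (C <= r_anchor[:, None]).mean(axis=1)
        for j, g in enumerate(genes):
            if g == anchor:
                continue
            cand = (r_anchor[j] >= r_min and ranks[j] >= quantile
                    and p_adj[j] < alpha)
            rows.append({"gene": g, "cell_group": group,
                         "r": float(r_anchor[j]), "p_adj": float(p_adj[j]),
                         "quantile_rank": float(ranks[j]), "candidate": cand})
    return pd.DataFrame(rows)


def arg_network(table: pd.DataFrame, prune_below: float = 1.3,
                core_degree: int = 18) -> pd.DataFrame:
    """Bipartite gene x group network with edge weight e = r + 1; edges with
    e < ``prune_below`` dropped; gene degree = surviving edges; core IEGs
    have degree > ``core_degree``."""
    if table.empty:
        raise ValueError("empty ARG table")
    cand = table[table["candidate"]] if "candidate" in table else table
    genes = sorted(set(cand["gene"]))
    sub = table[table["gene"].isin(genes)].copy()
    sub["e"] = sub["r"] + 1.0
    kept = sub[sub["e"] >= prune_below]
    degree = kept.groupby("gene").size().reindex(genes, fill_value=0)
    return pd.DataFrame({
        "gene": genes,
        "degree": degree.values,
        "core_ieg": degree.values > core_degree,
    })


def arg_clusters(table: pd.DataFrame, k: int = 7) -> pd.Series:
    """Ward agglomeration of candidate genes on their per-group anchor
    correlations (missing groups imputed 0), cut into exactly k clusters."""
    cand_genes = sorted(set(table.loc[table["candidate"], "gene"]))
    if len(cand_genes) < k:
        raise ValueError(f"{len(cand_genes)} candidate genes < k={k}")
    mat = (table[table["gene"].isin(cand_genes)]
           .pivot_table(index="gene", columns="cell_group", values="r",
                        fill_value=0.0)
           .reindex(cand_genes))
    Z = hierarchy.linkage(mat.values, method="ward")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=cand_genes, name="arg_cluster")


def geneset_overlap(set_a, set_b, universe, n_comparisons: int = 1):
    """One-sided Fisher's exact test of overlap between two gene sets within
    a universe; p Bonferroni-multiplied by ``n_comparisons`` (capped at 1)."""
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    a, b = set(set_a) & uni, set(set_b) & uni
    n11 = len(a & b)
    n12 = len(a - b)
    n21 = len(b - a)
    n22 = len(uni - a - b)
    odds = (n11 * n22) / (n12 * n21) if n12 * n21 > 0 else np.inf
    p = fisher_exact([[n11, n12], [n21, n22]], alternative="greater").pvalue
    return odds, min(p * n_comparisons, 1.0)
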