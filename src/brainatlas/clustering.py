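"""Recursive cluster discovery.

Each round: (1) binomial variable-gene selection, (2) square-root transform,
(3) cosine kNN (k=50) -> Jaccard shared-nearest-neighbour graph, (4) Leiden
sweep under the Constant Potts Model to the lowest resolution giving >= 2
clusters with a largest/second-largest size ratio <= 20, discarding clusters
smaller than sqrt(N). Recursion stops when the SNN graph is multi-component,
the sweep finds no valid partition, or the children lack three discrete
marker genes in each direction (Mann-Whitney U + nonzero-fraction rules);
a merge is reverted if one further round of subclustering yields children
that do pass (a continuous split hiding discrete structure one level down).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from sklearn.neighbors import NearestNeighbors

from .synthetic import CellProfileMatrix

__all__ = [
    "ClusteringConfig",
    "ClusterTree",
    "MarkerTestResult",
    "select_variable_genes",
    "build_snn",
    "leiden_sweep",
    "test_cluster_markers",
    "iterative_cluster",
]


@dataclass
class ClusteringConfig:
    k_neighbors: int = 50
    min_deficit: float = 0.05  # variable gene: observed <= expected - deficit
    resolution_grid: tuple = tuple(np.geomspace(1e-6, 1.0, 40))
    max_size_ratio: float = 20.0
    min_markers: int = 3
    alpha: float = 0.01  # Mann-Whitney two-sided, Bonferroni over genes tested
    low_max: float = 0.10  # marker: nonzero fraction in low population < 10%
    min_diff: float = 0.20  # marker: high side at least 20% higher
    max_depth: int = 20
    seed: int = 0


@dataclass
class MarkerTestResult:
    """Per-(leaf, direction) marker evidence against the sibling union."""

    table: pd.DataFrame  # columns: cluster, gene, direction, p, p_adj, frac_high, frac_low, diff, passed
    counts: dict  # (cluster, direction) -> number of passing genes
    decision: str  # "keep" | "merge"


@dataclass
class ClusterTree:
    """Result of the recursive clustering: nested nodes, terminal leaves,
    per-node discards and per-leaf marker tables."""

    nodes: dict = field(default_factory=dict)  # id -> node record
    leaves: list = field(default_factory=list)
    discarded: dict = field(default_factory=dict)  # node id -> list of cell idx

    def add_node(self, node_id, parent, members, **extra):
        self.nodes[node_id] = {
            "id": node_id,
            "parent": parent,
            "members": members,
            "children": [],
            "variable_genes": extra.pop("variable_genes", None),
            "resolution": extra.pop("resolution", None),
            "termination": extra.pop("termination", None),
            **extra,
        }
        if parent is not None:
            self.nodes[parent]["children"].append(node_id)

    def leaf_assignments(self, n_cells: int) -> np.ndarray:
        """Leaf label per cell; discarded cells get ''. """
        labels = np.full(n_cells, "", dtype=object)
        for leaf in self.leaves:
            labels[self.nodes[leaf]["members"]] = leaf
        return labels

    def all_discarded(self) -> np.ndarray:
        out = [np.asarray(v, dtype=int) for v in self.discarded.values()]
        return np.concatenate(out) if out else np.array([], dtype=int)


def select_variable_genes(cells: CellProfileMatrix, min_deficit: float = 0.05,
                          gene_subset: np.ndarray | None = None) -> list[str]:
    """Binomial-model variable genes.

    Per gene, p = summed counts / total UMIs; per cell lambda = n_cell * p;
    the expected nonzero fraction is mean_cells(1 - exp(-lambda)). A gene is
    selected when its observed nonzero fraction falls at least ``min_deficit``
    below expectation (discreteness the homogeneous model cannot explain).
    """
    X = cells.counts
    if X.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    total = X.sum()
    if total <= 0:
        raise ValueError("total counts must be positive")
    depths = cells.depths().astype(float)
    gene_sums = np.asarray(X.sum(axis=0)).ravel().astype(float)
    p = gene_sums / total
    observed = np.asarray((X > 0).mean(axis=0)).ravel()

    expected = np.empty_like(p)
    chunk = 512
    for s in range(0, p.size, chunk):
        lam = np.outer(depths, p[s:s + chunk])
        expected[s:s + chunk] = (1.0 - np.exp(-lam)).mean(axis=0)
    deficit = expected - observed
    sel = np.flatnonzero(deficit >= min_deficit)
    return [cells.gene_ids[i] for i in sel]


def _knn_adjacency(X: np.ndarray, k: int, metric: str = "cosine") -> sp.csr_matrix:
    """Row-stochastic 0/1 kNN adjacency (self excluded)."""
    n = X.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of observations")
    nn = NearestNeighbors(n_neighbors=k + 1, metric=metric)
    nn.fit(X)
    _, idx = nn.kneighbors(X)
    # drop self wherever present; otherwise drop the farthest to keep k
    rows = np.repeat(np.arange(n), k)
    cols = np.empty((n, k), dtype=int)
    for i in range(n):
        nbrs = idx[i][idx[i] != i][:k]
        if nbrs.size < k:  # degenerate ties; pad with nearest non-self repeats
            pad = [j for j in idx[i] if j != i]
            nbrs = np.asarray((list(nbrs) + pad)[:k])
        cols[i] = nbrs
    return sp.csr_matrix(
        (np.ones(n * k, dtype=np.int32), (rows, cols.ravel())), shape=(n, n)
    )


def snn_from_knn(adj: sp.csr_matrix, k: int) -> sp.coo_matrix:
    """Jaccard SNN weights from a kNN adjacency: |A∩B| / (2k − |A∩B|)."""
    shared = (adj @ adj.T).tocoo()
    mask = shared.row < shared.col
    r, c, s = shared.row[mask], shared.col[mask], shared.data[mask].astype(float)
    w = s / (2 * k - s)
    keep = w > 0
    n = adj.shape[0]
    return sp.coo_matrix((w[keep], (r[keep], c[keep])), shape=(n, n))


def build_snn(cells: CellProfileMatrix, genes: list[str], k: int = 50) -> ig.Graph:
    """Square-root transform on the selected genes, cosine kNN (self excluded),
    then the Jaccard shared-neighbour graph.

    Cells whose selected-gene row is all zero have no cosine direction; their
    neighbours are found on the square root of the full count matrix instead.
    """
    gi = {g: i for i, g in enumerate(cells.gene_ids)}
    cols = [gi[g] for g in genes]
    X = np.sqrt(cells.counts[:, cols].toarray())
    zero = X.sum(axis=1) == 0
    if zero.any():
        full = np.sqrt(cells.counts.toarray())
        # cosine distance of zero rows to everything on the full matrix
        norms = np.linalg.norm(full, axis=1)
        norms[norms == 0] = 1.0
        unit = full / norms[:, None]
        adj = _knn_adjacency(X[~zero], k) if (~zero).sum() > k else None
        # rebuild a combined adjacency with fallback rows
        n = X.shape[0]
        rows, cols_l = [], []
        nonzero_idx = np.flatnonzero(~zero)
        if adj is not None:
            a = adj.tocoo()
            rows.extend(nonzero_idx[a.row].tolist())
            cols_l.extend(nonzero_idx[a.col].tolist())
        for i in np.flatnonzero(zero):
            sims = unit @ unit[i]
            sims[i] = -np.inf
            nbrs = np.argpartition(-sims, k)[:k]
            rows.extend([i] * k)
            cols_l.extend(nbrs.tolist())
        adj = sp.csr_matrix((np.ones(len(rows), dtype=np.int32), (rows, cols_l)),
                            shape=(n, n))
        adj.data = np.minimum(adj.data, 1)
    else:
        adj = _knn_adjacency(X, k)
    snn = snn_from_knn(adj, k)
    g = ig.Graph(n=adj.shape[0],
                 edges=list(zip(snn.row.tolist(), snn.col.tolist())),
                 edge_attrs={"weight": snn.data.tolist()})
    return g


def leiden_sweep(graph: ig.Graph, N: int, config: ClusteringConfig | None = None,
                 seed: int = 0):
    """Constant-Potts Leiden resolution sweep.

    Returns ``(labels, resolution, discarded_idx)`` at the lowest resolution
    giving >= 2 clusters with size ratio <= 20 (clusters below sqrt(N)
    discarded), or ``(None, reason, [])`` with reason 'disconnected_trivial'
    (multi-component graph: homogeneous stop) or 'no_split'.
    """
    cfg = config or ClusteringConfig()
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    if not graph.is_connected():
        return None, "disconnected_trivial", []
    min_size = np.sqrt(N)
    for res in cfg.resolution_grid:
        part = leidenalg.find_partition(
            graph,
            leidenalg.CPMVertexPartition,
            weights="weight",
            resolution_parameter=float(res),
            seed=seed,
            n_iterations=2,
        )
        labels = np.asarray(part.membership)
        sizes = np.sort(np.bincount(labels))[::-1]
        if len(sizes) < 2 or sizes[0] / sizes[1] > cfg.max_size_ratio:
            continue
        keep_clusters = [c for c in np.unique(labels)
                         if (labels == c).sum() >= min_size]
        if len(keep_clusters) < 2:
            continue
        discarded = np.flatnonzero(~np.isin(labels, keep_clusters))
        out = labels.astype(object)
        out[discarded] = None
        return out, float(res), discarded.tolist()
    return None, "no_split", []


def _nonzero_fractions(X: sp.csr_matrix) -> np.ndarray:
    return np.asarray((X > 0).mean(axis=0)).ravel()


def test_cluster_markers(cells: CellProfileMatrix, labels: np.ndarray,
                         config: ClusteringConfig | None = None) -> MarkerTestResult:
    """Discrete-marker test of a partition: each cluster versus the union of
    its siblings, in both directions.

    A gene passes for (cluster, direction) when the Mann-Whitney two-sided
    p (Bonferroni over all genes at this node) is below alpha, the low
    population expresses it in < 10% of cells, and the high population's
    nonzero rate is at least 20 points higher. Decision is 'keep' iff every
    cluster has >= 3 passing genes in each direction; a single-cell cluster
    forces a merge (the U test is undefined there).
    """
    cfg = config or ClusteringConfig()
    labs = np.asarray(labels)
    valid = np.array([l is not None and l == l for l in labs], dtype=bool)
    uniq = sorted({l for l in labs[valid]}, key=str)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    n_genes = cells.n_genes
    rows = []
    counts = {}
    decision = "keep"
    bonf = n_genes * 1.0
    for cl in uniq:
        in_cl = valid & (labs == cl)
        rest = valid & (labs != cl)
        if in_cl.sum() < 2:
            decision = "merge"
            counts[(cl, "up")] = counts[(cl, "down")] = 0
            continue
        hi = cells.counts[np.flatnonzero(in_cl)]
        lo = cells.counts[np.flatnonzero(rest)]
        f_cl = _nonzero_fractions(hi)
        f_rest = _nonzero_fractions(lo)
        for direction in ("up", "down"):
            if direction == "up":
                f_hi, f_lo = f_cl, f_rest
            else:
                f_hi, f_lo = f_rest, f_cl
            cand = np.flatnonzero((f_lo < cfg.low_max) & (f_hi >= f_lo + cfg.min_diff))
            passed = []
            if cand.size:
                x = hi[:, cand].toarray()
                y = lo[:, cand].toarray()
                p = mannwhitneyu(x, y, alternative="two-sided", axis=0).pvalue
                p_adj = np.minimum(p * bonf, 1.0)
                ok = p_adj < cfg.alpha
                passed = cand[ok]
                for j, gidx in enumerate(cand):
                    rows.append({
                        "cluster": cl, "gene": cells.gene_ids[gidx],
                        "direction": direction, "p": float(p[j]),
                        "p_adj": float(p_adj[j]),
                        "frac_high": float(f_hi[gidx]), "frac_low": float(f_lo[gidx]),
                        "diff": float(f_hi[gidx] - f_lo[gidx]),
                        "passed": bool(ok[j]),
                    })
            counts[(cl, direction)] = int(len(passed))
            if len(passed) < cfg.min_markers:
                decision = "merge"
    table = pd.DataFrame(rows, columns=["cluster", "gene", "direction", "p",
                                        "p_adj", "frac_high", "frac_low",
                                        "diff", "passed"])
    return MarkerTestResult(table=table, counts=counts, decision=decision)


def _node_seed(master_seed: int, node_id: str) -> int:
    return (master_seed * 1_000_003 + zlib.crc32(node_id.encode())) % (2**31 - 1)


def _split_once(cells, members, config, node_id):
    """One round: variable genes -> SNN -> sweep. Returns dict with either a
    partition (labels over `members`) or a termination reason."""
    sub = cells.subset(members)
    genes = select_variable_genes(sub, config.min_deficit)
    if len(genes) == 0 or len(members) <= config.k_neighbors:
        return {"termination": "no_split", "variable_genes": genes}
    graph = build_snn(sub, genes, config.k_neighbors)
    labels, res_or_reason, discarded = leiden_sweep(
        graph, len(members), config, seed=_node_seed(config.seed, node_id))
    if labels is None:
        return {"termination": res_or_reason, "variable_genes": genes}
    return {"labels": labels, "resolution": res_or_reason,
            "discarded": discarded, "variable_genes": genes}


def iterative_cluster(cells: CellProfileMatrix,
                      config: ClusteringConfig | None = None) -> ClusterTree:
    """Recursive clustering orchestrator; deterministic for a fixed seed.

    The marker-based termination has one exception: when a partition fails
    the marker test, each child is subclustered one level; if that finer
    partition passes the marker test, the original children are retained
    (the first split was along a continuous axis hiding discrete types).
    """
    cfg = config or ClusteringConfig()
    tree = ClusterTree()
    all_members = np.arange(cells.n_cells)
    tree.add_node("root", None, all_members)

    def recurse(node_id: str, members: np.ndarray, depth: int):
        if depth > cfg.max_depth:
            raise RecursionError(f"clustering recursion exceeded {cfg.max_depth}")
        res = _split_once(cells, members, cfg, node_id)
        node = tree.nodes[node_id]
        node["variable_genes"] = res.get("variable_genes")
        if "labels" not in res:
            node["termination"] = res["termination"]
            tree.leaves.append(node_id)
            return
        labels = res["labels"]
        node["resolution"] = res["resolution"]

        sub = cells.subset(members)
        mres = test_cluster_markers(sub, labels, cfg)
        node["marker_counts"] = {f"{k[0]}|{k[1]}": v for k, v in mres.counts.items()}
        if mres.decision == "merge" and not _continuous_split_exception(sub, labels, cfg, node_id):
            node["termination"] = "no_markers_merged"
            tree.leaves.append(node_id)
            return
        # split is kept: record the sqrt(N) discards of this round
        if res["discarded"]:
            tree.discarded[node_id] = members[np.asarray(res["discarded"], dtype=int)].tolist()
        uniq = sorted({l for l in labels if l is not None})
        for ci, cl in enumerate(uniq):
            child_id = f"{node_id}.{ci}"
            child_members = members[np.flatnonzero(
                np.array([l == cl for l in labels], dtype=bool))]
            tree.add_node(child_id, node_id, child_members)
            recurse(child_id, child_members, depth + 1)

    recurse("root", all_members, 0)

    # leaf marker tables: each terminal leaf vs its sibling leaves
    for leaf in tree.leaves:
        parent = tree.nodes[leaf]["parent"]
        if parent is None:
            tree.nodes[leaf]["termination"] = tree.nodes[leaf].get("termination") or "leaf"
            continue
        if tree.nodes[leaf].get("termination") is None:
            tree.nodes[leaf]["termination"] = "leaf"
    return tree


def _continuous_split_exception(sub: CellProfileMatrix, labels: np.ndarray,
                                cfg: ClusteringConfig, node_id: str) -> bool:
    """Look exactly one level deeper: subcluster each failing child once; if
    the pooled finer partition passes the marker test, retain the children."""
    uniq = sorted({l for l in labels if l is not None}, key=str)
    fine = np.array([None if l is None else f"{l}" for l in labels], dtype=object)
    any_finer = False
    for ci, cl in enumerate(uniq):
        mask = np.array([l == cl for l in labels], dtype=bool)
        members = np.flatnonzero(mask)
        res = _split_once(sub, members, cfg, f"{node_id}.x{ci}")
        if "labels" in res:
            any_finer = True
            for local_i, lab in enumerate(res["labels"]):
                gidx = members[local_i]
                fine[gidx] = None if lab is None else f"{cl}:{lab}"
    if not any_finer:
        return False
    uniq_fine = {l for l in fine if l is not None}
    if len(uniq_fine) < 2:
        return False
    mres = test_cluster_markers(sub, fine, cfg)
    return mres.decision == "keep"
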