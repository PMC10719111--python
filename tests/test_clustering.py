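"""Recursive clustering: variable-gene model, SNN construction, the CPM
resolution sweep and the discrete-marker termination test."""

import itertools

import igraph as ig
import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from brainatlas.clustering import (ClusteringConfig, build_snn,
                                   iterative_cluster, leiden_sweep,
                                   select_variable_genes, snn_from_knn)
from brainatlas.clustering import test_cluster_markers as marker_test
from brainatlas.synthetic import GeneratorConfig, build_ground_truth, simulate_cells

from conftest import make_cells


# ---------------------------------------------------------------- variable genes

def test_bimodal_gene_selected():
    """A gene expressed at high level in half the cells and absent in the
    other half falls far below the pooled-binomial expectation."""
    rng = np.random.default_rng(0)
    n = 400
    counts = rng.poisson(5, size=(n, 30))
    counts[:, 0] = 0
    counts[: n // 2, 0] = rng.poisson(20, size=n // 2)  # ~p=0.01 of bulk
    cells = make_cells(counts)
    sel = select_variable_genes(cells)
    assert "g0" in sel


def test_homogeneous_gene_not_selected():
    rng = np.random.default_rng(1)
    counts = rng.poisson(3, size=(2000, 40))
    cells = make_cells(counts)
    sel = select_variable_genes(cells)
    assert sel == []


def test_all_zero_gene_not_selected():
    rng = np.random.default_rng(2)
    counts = rng.poisson(3, size=(100, 10))
    counts[:, 4] = 0
    cells = make_cells(counts)
    assert "g4" not in select_variable_genes(cells)


def test_expected_fraction_arithmetic():
    """Hand-checkable deficit: every cell at depth 1,000, gene at p = 0.01
    observed in exactly half the cells -> expected 1 - e^-10 ~ 0.99995."""
    n = 200
    counts = np.zeros((n, 2), dtype=int)
    counts[:, 1] = 990
    counts[: n // 2, 0] = 20
    counts[: n // 2, 1] = 980
    cells = make_cells(counts)
    sel = select_variable_genes(cells)
    assert "g0" in sel


# ---------------------------------------------------------------- SNN graph

def test_snn_identical_and_disjoint_neighbour_sets():
    adj = np.zeros((6, 6), dtype=int)
    # cells 0 and 1 share the same 2 neighbours {2, 3}; 4 and 5 use {0, 1}
    adj[0, [2, 3]] = 1
    adj[1, [2, 3]] = 1
    adj[2, [4, 5]] = 1
    adj[3, [0, 1]] = 1
    adj[4, [0, 1]] = 1
    adj[5, [0, 1]] = 1
    import scipy.sparse as sp
    snn = snn_from_knn(sp.csr_matrix(adj), k=2).toarray()
    snn = snn + snn.T
    assert snn[0, 1] == 1.0          # identical sets -> Jaccard 1
    assert snn[0, 2] == 0.0          # disjoint sets -> no edge
    assert snn[4, 5] == 1.0


def test_snn_matches_brute_force_on_two_blobs():
    rng = np.random.default_rng(3)
    # two blobs with complementary gene support (cosine separates direction)
    counts = np.vstack([
        np.hstack([rng.poisson(50, (15, 4)), rng.poisson(2, (15, 4))]),
        np.hstack([rng.poisson(2, (15, 4)), rng.poisson(50, (15, 4))]),
    ]) + 1
    cells = make_cells(counts)
    k = 5
    g = build_snn(cells, cells.gene_ids, k=k)
    # brute-force Jaccard from the cosine kNN sets
    Xs = np.sqrt(counts)
    sims = Xs @ Xs.T / (np.linalg.norm(Xs, axis=1)[:, None]
                        * np.linalg.norm(Xs, axis=1)[None, :])
    np.fill_diagonal(sims, -np.inf)
    nbrs = [set(np.argsort(-sims[i])[:k]) for i in range(30)]
    expected = {}
    for i, j in itertools.combinations(range(30), 2):
        inter = len(nbrs[i] & nbrs[j])
        if inter:
            expected[(i, j)] = inter / len(nbrs[i] | nbrs[j])
    got = {tuple(sorted(e.tuple)): e["weight"] for e in g.es}
    assert got == pytest.approx(expected)
    intra = [w for (i, j), w in got.items() if (i < 15) == (j < 15)]
    inter = [w for (i, j), w in got.items() if (i < 15) != (j < 15)]
    assert not inter or min(intra) > max(inter)


def test_snn_zero_row_fallback():
    rng = np.random.default_rng(4)
    counts = rng.poisson(5, size=(40, 10))
    counts[3, :2] = 0  # zero on the "selected" genes below
    cells = make_cells(counts)
    g = build_snn(cells, ["g0", "g1"], k=5)
    assert g.vcount() == 40  # fallback cell present with neighbours
    assert g.degree(3) > 0


# ---------------------------------------------------------------- Leiden sweep

def _two_cliques(n=50):
    g = ig.Graph.Full(n) + ig.Graph.Full(n)
    g.add_edge(0, n)  # single bridge keeps it connected
    g.es["weight"] = 1.0
    return g


def test_sweep_splits_two_cliques():
    g = _two_cliques(50)
    labels, res, discarded = leiden_sweep(g, 100, seed=1)
    assert labels is not None
    assert discarded == []
    groups = {frozenset(np.flatnonzero([l == c for l in labels]))
              for c in set(labels)}
    assert groups == {frozenset(range(50)), frozenset(range(50, 100))}


def test_sweep_single_clique_no_split():
    g = ig.Graph.Full(80)
    g.es["weight"] = 1.0
    labels, reason, _ = leiden_sweep(g, 80, seed=1)
    assert labels is None and reason == "no_split"


def test_sweep_disconnected_stops():
    g = ig.Graph.Full(30) + ig.Graph.Full(30)  # no bridge
    g.es["weight"] = 1.0
    labels, reason, _ = leiden_sweep(g, 60, seed=1)
    assert labels is None and reason == "disconnected_trivial"


def test_size_ratio_rule_arithmetic():
    # a {980, 20} partition has ratio 49 > 20 and must not be accepted
    assert 980 / 20 > 20


# ---------------------------------------------------------------- marker test

def _fraction_cells(frac_a, frac_b, n=200, depth=60):
    """Two clusters; per gene, nonzero fractions approx frac_a / frac_b."""
    rng = np.random.default_rng(5)
    g = len(frac_a)
    counts = np.zeros((2 * n, g + 1), dtype=int)
    counts[:, g] = depth
    for j in range(g):
        counts[:n, j] = (rng.random(n) < frac_a[j]) * rng.poisson(4, n).clip(1)
        counts[n:, j] = (rng.random(n) < frac_b[j]) * rng.poisson(4, n).clip(1)
    cells = make_cells(counts)
    labels = np.array([0] * n + [1] * n, dtype=object)
    return cells, labels


def test_markers_keep_when_both_directions_pass():
    # 4 genes up in each cluster at 60% vs 2%
    fa = [0.6] * 4 + [0.02] * 4
    fb = [0.02] * 4 + [0.6] * 4
    cells, labels = _fraction_cells(fa, fb)
    res = marker_test(cells, labels)
    assert res.decision == "keep"
    assert res.counts[(0, "up")] >= 3 and res.counts[(0, "down")] >= 3


def test_markers_merge_when_identical():
    fa = [0.5] * 6
    cells, labels = _fraction_cells(fa, fa)
    res = marker_test(cells, labels)
    assert res.decision == "merge"


def test_low_side_rule_excludes_25_vs_15():
    """25% vs 15% nonzero fails the '<10% in the low population' rule even
    though the difference might be significant."""
    fa = [0.25] * 6 + [0.6] * 4 + [0.02] * 4
    fb = [0.15] * 6 + [0.02] * 4 + [0.6] * 4
    cells, labels = _fraction_cells(fa, fb)
    res = marker_test(cells, labels)
    genes_passed = set(res.table.loc[res.table["passed"], "gene"])
    assert not genes_passed & {f"g{j}" for j in range(6)}


def test_single_cell_cluster_forces_merge():
    rng = np.random.default_rng(6)
    cells = make_cells(rng.poisson(5, (20, 10)))
    labels = np.array([0] + [1] * 19, dtype=object)
    res = marker_test(cells, labels)
    assert res.decision == "merge"


def test_marker_flags_match_brute_force():
    """Pass flags equal a direct dense reimplementation of the three
    criteria on random small matrices."""
    cfg = ClusteringConfig()
    rng = np.random.default_rng(7)
    for rep in range(20):
        n, g = 60, 25
        counts = rng.poisson(rng.uniform(0, 3, size=g), size=(n, g))
        onoff = rng.random((2, g)) < 0.4
        counts[:30] *= onoff[0]
        counts[30:] *= onoff[1]
        counts[:, -1] = 1  # keep depths positive
        cells = make_cells(counts)
        labels = np.array([0] * 30 + [1] * 30, dtype=object)
        res = marker_test(cells, labels, cfg)
        dense = counts.astype(float)
        for cl, direction in [(0, "up"), (0, "down"), (1, "up"), (1, "down")]:
            in_cl = labels == cl
            hi_mask = in_cl if direction == "up" else ~in_cl
            expected = set()
            for j in range(g):
                f_hi = (dense[hi_mask, j] > 0).mean()
                f_lo = (dense[~hi_mask, j] > 0).mean()
                if not (f_lo < cfg.low_max and f_hi >= f_lo + cfg.min_diff):
                    continue
                p = mannwhitneyu(dense[hi_mask, j], dense[~hi_mask, j],
                                 alternative="two-sided").pvalue
                if min(p * g, 1.0) < cfg.alpha:
                    expected.add(f"g{j}")
            got = set(res.table.loc[(res.table["cluster"] == cl)
                                    & (res.table["direction"] == direction)
                                    & res.table["passed"], "gene"])
            assert got == expected, (rep, cl, direction)


# ---------------------------------------------------------------- recursion

def test_homogeneous_population_single_leaf():
    truth = build_ground_truth(GeneratorConfig(
        n_types=2, n_genes=200, n_markers_per_type=0, n_classes=1,
        type_jitter_sigma=0.0, seed=20))
    cells = simulate_cells(truth, 400, 3000, seed=21)
    tree = iterative_cluster(cells, ClusteringConfig(seed=1))
    assert tree.leaves == ["root"]
    assert tree.nodes["root"]["termination"] in ("no_split",
                                                 "disconnected_trivial",
                                                 "no_markers_merged")


def test_partition_property_and_marker_monotonicity(truth_small):
    cells = simulate_cells(truth_small, 1200, 5000, seed=22)
    tree3 = iterative_cluster(cells, ClusteringConfig(seed=2, min_markers=3))
    labels = tree3.leaf_assignments(cells.n_cells)
    discarded = set(tree3.all_discarded())
    in_leaf = {i for leaf in tree3.leaves
               for i in tree3.nodes[leaf]["members"]}
    assert in_leaf | discarded == set(range(cells.n_cells))
    assert not (in_leaf & discarded)
    assert (labels != "").sum() == len(in_leaf)
    # requiring more markers can only coarsen the tree
    tree5 = iterative_cluster(cells, ClusteringConfig(seed=2, min_markers=5))
    assert len(tree5.leaves) <= len(tree3.leaves)


def test_clustering_deterministic(truth_small):
    cells = simulate_cells(truth_small, 800, 4000, seed=23)
    t1 = iterative_cluster(cells, ClusteringConfig(seed=3))
    t2 = iterative_cluster(cells, ClusteringConfig(seed=3))
    assert t1.leaves == t2.leaves
    for leaf in t1.leaves:
        assert np.array_equal(t1.nodes[leaf]["members"],
                              t2.nodes[leaf]["members"])


def test_doublets_do_not_create_extra_leaves():
    truth = build_ground_truth(GeneratorConfig(
        n_types=2, n_genes=200, n_classes=1, doublet_rate=0.05, seed=24))
    cells = simulate_cells(truth, 1500, 5000, seed=25)
    tree = iterative_cluster(cells, ClusteringConfig(seed=4))
    assert 2 <= len(tree.leaves) <= 3
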