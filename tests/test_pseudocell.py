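"""Pseudocell construction, normalization and the ARG criteria."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from brainatlas.pseudocell import (arg_candidates, arg_clusters, arg_network,
                                   build_pseudocells, geneset_overlap,
                                   holm_adjust, normalize_pseudocells,
                                   pseudocell_size, quantile_normalize)
from brainatlas.synthetic import simulate_pseudocell_matrix

from conftest import make_cells


# ---------------------------------------------------------------- size rule

@pytest.mark.parametrize("n,s", [(10_000, 200.0), (500, 20.0), (2_500, 50.0),
                                 (1, 20.0), (1_000_000, 200.0)])
def test_pseudocell_size_rule(n, s):
    assert pseudocell_size(n) == s


# ---------------------------------------------------------------- construction

def test_forty_cells_make_two_pseudocells():
    rng = np.random.default_rng(0)
    cells = make_cells(rng.poisson(5, size=(40, 30)))
    labs = np.array(["T"] * 40, dtype=object)
    pcs = build_pseudocells(cells, labs, seed=1)
    assert pcs.counts.shape[0] == 2
    assert set(pcs.membership.values) == set(pcs.meta.index)
    assert pcs.membership.notna().all()


def test_small_type_is_single_pseudocell():
    rng = np.random.default_rng(1)
    cells = make_cells(rng.poisson(5, size=(15, 30)))
    pcs = build_pseudocells(cells, np.array(["T"] * 15, dtype=object), seed=1)
    assert pcs.counts.shape[0] == 1
    assert pcs.meta.iloc[0]["n_cells"] == 15


def test_pseudocells_never_span_types():
    rng = np.random.default_rng(2)
    cells = make_cells(rng.poisson(5, size=(120, 30)))
    labs = np.array(["A"] * 60 + ["B"] * 60, dtype=object)
    pcs = build_pseudocells(cells, labs, seed=2)
    for pc_id, grp in pcs.membership.groupby(pcs.membership.values):
        cell_types = {labs[int(c[1:])] for c in grp.index}
        assert len(cell_types) == 1


def test_aggregation_conserves_counts():
    rng = np.random.default_rng(3)
    counts = rng.poisson(4, size=(90, 25))
    cells = make_cells(counts)
    labs = np.array(["A"] * 45 + ["B"] * 45, dtype=object)
    pcs = build_pseudocells(cells, labs, seed=3)
    assert np.array_equal(
        np.asarray(pcs.counts.sum(axis=0)).ravel(), counts.sum(axis=0))


def test_separated_subpopulations_give_pure_pseudocells():
    rng = np.random.default_rng(4)
    a = rng.poisson(np.r_[np.full(10, 30.0), np.full(10, 1.0)], size=(40, 20))
    b = rng.poisson(np.r_[np.full(10, 1.0), np.full(10, 30.0)], size=(40, 20))
    cells = make_cells(np.vstack([a, b]))
    labs = np.array(["T"] * 80, dtype=object)
    pcs = build_pseudocells(cells, labs, seed=4)
    truth = np.array([0] * 40 + [1] * 40)
    for pc_id in pcs.meta.index:
        members = [int(c[1:]) for c in
                   pcs.membership[pcs.membership == pc_id].index]
        majority = max(truth[members].mean(), 1 - truth[members].mean())
        assert majority >= 0.9


# ---------------------------------------------------------------- normalization

def _pcs_from_counts(counts):
    cells = make_cells(counts)
    labs = np.array(["T"] * counts.shape[0], dtype=object)
    pcs = build_pseudocells(cells, labs, seed=5)
    return pcs


def test_normalization_moments():
    rng = np.random.default_rng(6)
    pcs = _pcs_from_counts(rng.poisson(5, size=(300, 40)))
    norm = normalize_pseudocells(pcs)
    live = [g for g in norm.columns if g not in pcs.zero_variance_genes]
    assert np.allclose(norm[live].mean(axis=0), 0.0, atol=1e-8)
    assert np.allclose(norm[live].std(axis=0, ddof=0), 1.0, atol=1e-6)


def test_identical_pseudocells_normalize_identically():
    row = np.full((2, 10), 7)
    import scipy.sparse as sp
    from brainatlas.pseudocell import PseudocellSet
    pcs = PseudocellSet(
        counts=sp.csr_matrix(row), membership=pd.Series(dtype=object),
        meta=pd.DataFrame(index=["p0", "p1"]),
        gene_ids=[f"g{j}" for j in range(10)])
    norm = normalize_pseudocells(pcs)
    assert np.allclose(norm.values, 0.0)
    assert set(pcs.zero_variance_genes) == set(pcs.gene_ids)


def test_quantile_normalization_preserves_within_sample_ranks():
    rng = np.random.default_rng(7)
    mat = rng.lognormal(0, 1, size=(5, 30))
    qn = quantile_normalize(mat)
    for i in range(5):
        assert np.array_equal(np.argsort(mat[i]), np.argsort(qn[i]))
    # column permutation equivariance
    perm = rng.permutation(30)
    qn_perm = quantile_normalize(mat[:, perm])
    assert np.allclose(qn_perm, qn[:, perm])


# ---------------------------------------------------------------- Holm

def test_holm_matches_brute_force():
    rng = np.random.default_rng(8)
    for _ in range(30):
        p = rng.random(rng.integers(1, 40))
        adj = holm_adjust(p)
        # brute force step-down
        m = p.size
        order = np.argsort(p)
        expected = np.empty(m)
        prev = 0.0
        for i, idx in enumerate(order):
            val = min((m - i) * p[idx], 1.0)
            prev = max(prev, val)
            expected[idx] = prev
        assert np.allclose(adj, expected)


# ---------------------------------------------------------------- ARG criteria

def test_planted_module_recovered():
    module = {f"Arg{i}": 0.8 for i in range(8)}
    norm = simulate_pseudocell_matrix(200, 300, module, "Fos", seed=9)
    groups = pd.Series(["g1"] * 200, index=norm.index)
    table = arg_candidates(norm, groups, "Fos")
    cand = set(table.loc[table["candidate"], "gene"])
    assert set(module) <= cand
    background = set(norm.columns) - set(module) - {"Fos"}
    assert len(cand & background) / len(background) <= 0.05


def test_anchor_excluded_from_candidates():
    norm = simulate_pseudocell_matrix(100, 50, {"Arg0": 0.7}, "Fos", seed=10)
    groups = pd.Series(["g"] * 100, index=norm.index)
    table = arg_candidates(norm, groups, "Fos")
    assert "Fos" not in set(table["gene"])


def test_r_threshold_is_hard():
    """A gene correlated at r < 0.3 is never a candidate regardless of p."""
    rng = np.random.default_rng(11)
    n = 5000  # huge n -> tiny p even for r ~ 0.25
    z = rng.standard_normal(n)
    g = 0.25 * z + np.sqrt(1 - 0.0625) * rng.standard_normal(n)
    norm = pd.DataFrame({"Fos": z, "gene": g,
                         **{f"b{i}": rng.standard_normal(n) for i in range(20)}})
    r, p = pearsonr(norm["Fos"], norm["gene"])
    assert r < 0.3 and p < 1e-10
    table = arg_candidates(norm, pd.Series(["g"] * n, index=norm.index), "Fos")
    row = table[table["gene"] == "gene"].iloc[0]
    assert not row["candidate"]


def test_group_too_small_skipped():
    norm = simulate_pseudocell_matrix(30, 40, {"Arg0": 0.7}, "Fos", seed=12)
    groups = pd.Series(["big"] * 25 + ["small"] * 5, index=norm.index)
    with pytest.warns(UserWarning, match="small"):
        table = arg_candidates(norm, groups, "Fos")
    assert set(table["cell_group"]) == {"big"}


# ---------------------------------------------------------------- network/clusters

def _table(rows):
    return pd.DataFrame(rows, columns=["gene", "cell_group", "r", "p_adj",
                                       "quantile_rank", "candidate"])


def test_network_prune_rule_boundary():
    rows = [("gA", f"grp{i}", 0.3, 0.0, 1.0, True) for i in range(19)]
    rows += [("gB", "grp0", 0.25, 0.0, 1.0, True)]  # e = 1.25 < 1.3 pruned
    net = arg_network(_table(rows)).set_index("gene")
    assert net.loc["gA", "degree"] == 19      # e = 1.3 kept (strict '< 1.3')
    assert bool(net.loc["gA", "core_ieg"])    # degree 19 > 18
    assert net.loc["gB", "degree"] == 0
    assert not bool(net.loc["gB", "core_ieg"])


def test_arg_clusters_split_orthogonal_modules():
    rows = []
    for i in range(5):
        for g in range(4):
            rows.append((f"m1_{i}", f"grpA{g}", 0.8, 0.0, 1.0, True))
            rows.append((f"m1_{i}", f"grpB{g}", 0.0, 1.0, 0.5, False))
            rows.append((f"m2_{i}", f"grpA{g}", 0.0, 1.0, 0.5, False))
            rows.append((f"m2_{i}", f"grpB{g}", 0.8, 0.0, 1.0, True))
    labels = arg_clusters(_table(rows), k=2)
    m1 = {labels[f"m1_{i}"] for i in range(5)}
    m2 = {labels[f"m2_{i}"] for i in range(5)}
    assert len(m1) == 1 and len(m2) == 1 and m1 != m2


def test_arg_clusters_duplicates_cocluster_and_k_bounds():
    rows = [(f"g{i}", "grp", 0.5, 0.0, 1.0, True) for i in range(4)]
    rows += [("g0dup", "grp", 0.5, 0.0, 1.0, True)]
    table = _table(rows)
    labels = arg_clusters(table, k=5)
    assert len(set(labels.values)) == 5  # k = genes -> singletons
    with pytest.raises(ValueError):
        arg_clusters(table, k=6)


# ---------------------------------------------------------------- overlap test

def test_geneset_overlap_cross_product():
    universe = [f"g{i}" for i in range(100)]
    odds, p = geneset_overlap(universe[:10], universe[5:15], universe)
    assert odds == pytest.approx((5 * 85) / (5 * 5))
    odds2, p2 = geneset_overlap(universe[:10], universe[:10], universe)
    assert np.isinf(odds2) and p2 < 1e-10


def test_geneset_overlap_disjoint_and_bonferroni():
    universe = [f"g{i}" for i in range(20)]
    odds, p = geneset_overlap(universe[:10], universe[10:], universe)
    assert odds < 1 and p == 1.0
    _, p_corr = geneset_overlap(universe[:10], universe[5:15], universe,
                                n_comparisons=1000)
    assert p_corr <= 1.0
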