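"""Bead-level cell-type decomposition with a pair-frequency confidence score.

Each eligible bead (>= 150 total UMIs, >= 20 within the region's tailored
gene list) is decomposed against its region's reference profiles under a
Poisson likelihood: counts y_g ~ Poisson(n_b * mu_g) with
mu_g = sum_t w_t * theta_{t,g}, w >= 0, sum(w) <= 1. Candidate types come
from full-mode fits with two ridge penalties (0.01, 0.001) plus single-type
fits; explicit pairs are scored with one member from the 10 most likely
candidates. Pairs within 30 natural-log-likelihood units of the best are
"well fitting"; a type's confidence is its occurrence share among them
(maximum 0.5; above 0.3 the mapping is called confident).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .synthetic import BeadMatrix, CellProfileMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MappingConfig",
    "ReferenceProfiles",
    "BeadMapping",
    "build_region_reference",
    "filter_beads",
    "fit_weights",
    "prefilter_celltypes",
    "score_pairs",
    "confidence_scores",
    "map_beads",
]


@dataclass
class MappingConfig:
    ridge_strengths: tuple = (0.01, 0.001)
    w_min: float = 0.01
    n_top: int = 10
    likelihood_window: float = 30.0
    confidence_threshold: float = 0.3
    min_bead_umis: int = 150
    min_tailored_umis: int = 20
    min_region_cells: int = 50
    min_total_cells: int = 100
    max_tailored_genes: int = 5000
    tol: float = 1e-8
    max_iter: int = 1000


@dataclass
class ReferenceProfiles:
    """Per-region decomposition reference: type expression proportions,
    cell counts and the tailored (most differential) gene list."""

    region: str
    types: list[str]
    theta: np.ndarray  # types x genes (full universe), rows sum to 1
    cells_per_type: dict
    tailored_genes: list[str]
    gene_ids: list[str]

    def tailored_theta(self) -> tuple[np.ndarray, np.ndarray]:
        gi = {g: i for i, g in enumerate(self.gene_ids)}
        idx = np.asarray([gi[g] for g in self.tailored_genes], dtype=int)
        return self.theta[:, idx], idx


@dataclass
class BeadMapping:
    """Per-bead decomposition results (wide per-bead table plus a long
    per-type confidence table)."""

    beads: pd.DataFrame  # bead_id, region, eligible, best pair + weights, loglik
    confidences: pd.DataFrame  # bead_id, type, confidence, confident
    pair_tables: dict = field(default_factory=dict)  # bead_id -> scored pair DataFrame


def _one_vs_rest_min_p(X, labels, types) -> np.ndarray:
    """Per gene, the smallest Mann-Whitney one-vs-rest p across types."""
    min_p = np.full(X.shape[1], 1.0)
    labs = np.asarray(labels)
    for t in types:
        mask = labs == t
        x = X[np.flatnonzero(mask)].toarray()
        y = X[np.flatnonzero(~mask)].toarray()
        with np.errstate(all="ignore"):
            p = mannwhitneyu(x, y, alternative="two-sided", axis=0).pvalue
        p = np.where(np.isnan(p), 1.0, p)
        min_p = np.minimum(min_p, p)
    return min_p


def build_region_reference(cells: CellProfileMatrix, leaf_assignments,
                           region: str, config: MappingConfig | None = None) -> ReferenceProfiles:
    """Reference for one large-scale region.

    Types need >= ``min_region_cells`` cells whose region tag matches and
    >= ``min_total_cells`` overall; theta is the per-type mean count vector
    normalized to proportions. The tailored list ranks genes by their
    smallest one-vs-rest Mann-Whitney p across the reference's types,
    truncated at ``max_tailored_genes``.
    """
    cfg = config or MappingConfig()
    labs = np.asarray(leaf_assignments, dtype=object)
    regions = cells.cell_meta["region"].values
    eligible = []
    cells_per_type = {}
    for t in pd.unique(labs):
        if t in ("", None):
            continue
        total = int((labs == t).sum())
        in_region = int(((labs == t) & (regions == region)).sum())
        if total >= cfg.min_total_cells and in_region >= cfg.min_region_cells:
            eligible.append(t)
            cells_per_type[t] = total
    eligible = sorted(eligible)
    if len(eligible) < 2:
        raise ValueError(
            f"region {region!r} has {len(eligible)} eligible types; "
            "decomposition needs at least 2")
    theta = np.zeros((len(eligible), cells.n_genes))
    for i, t in enumerate(eligible):
        mean_counts = np.asarray(
            cells.counts[np.flatnonzero(labs == t)].mean(axis=0)).ravel()
        theta[i] = mean_counts / mean_counts.sum()

    ref_mask = np.isin(labs, eligible)
    sub = cells.subset(ref_mask)
    min_p = _one_vs_rest_min_p(sub.counts, labs[ref_mask], eligible)
    order = np.lexsort((np.asarray(cells.gene_ids, dtype=object), min_p))
    tailored = [cells.gene_ids[i] for i in order[: cfg.max_tailored_genes]]
    return ReferenceProfiles(region=region, types=list(eligible), theta=theta,
                             cells_per_type=cells_per_type,
                             tailored_genes=tailored, gene_ids=list(cells.gene_ids))


def filter_beads(beads: BeadMatrix, tailored_genes, config: MappingConfig | None = None) -> np.ndarray:
    """Eligibility: >= 150 UMIs over all genes and >= 20 within the tailored
    gene list."""
    cfg = config or MappingConfig()
    gi = {g: i for i, g in enumerate(beads.gene_ids)}
    idx = np.asarray([gi[g] for g in tailored_genes if g in gi], dtype=int)
    total = beads.depths()
    tailored = np.asarray(beads.counts[:, idx].sum(axis=1)).ravel()
    return (total >= cfg.min_bead_umis) & (tailored >= cfg.min_tailored_umis)


def _project_capped_simplex(w: np.ndarray) -> np.ndarray:
    """Euclidean projection onto {w >= 0, sum(w) <= 1}."""
    w = np.maximum(w, 0.0)
    s = w.sum()
    if s <= 1.0:
        return w
    # project onto the simplex sum(w) = 1 (sorted-threshold algorithm)
    u = np.sort(w)[::-1]
    css = np.cumsum(u)
    rho = np.flatnonzero(u * np.arange(1, w.size + 1) > (css - 1.0))[-1]
    tau = (css[rho] - 1.0) / (rho + 1.0)
    return np.maximum(w - tau, 0.0)


def fit_weights(y: np.ndarray, theta: np.ndarray, depth: float,
                ridge_strength: float = 0.0,
                config: MappingConfig | None = None):
    """Maximize the Poisson log-likelihood sum_g [y_g log(n mu_g) - n mu_g]
    minus ridge_strength * n * ||w||^2 over w >= 0, sum(w) <= 1 by projected
    gradient with backtracking. Returns (w, unpenalized log-likelihood)."""
    cfg = config or MappingConfig()
    y = np.asarray(y, dtype=float).ravel()
    theta = np.atleast_2d(theta)
    T = theta.shape[0]
    n = float(depth)
    pos = y > 0
    ypos = y[pos]
    th_pos = theta[:, pos]

    def objective(w):
        mu = th_pos.T @ w
        return -(ypos @ np.log(np.maximum(n * mu, 1e-300))) + n * w.sum() \
            + ridge_strength * n * (w @ w)

    def gradient(w):
        mu = np.maximum(th_pos.T @ w, 1e-300)
        return -(th_pos @ (ypos / mu)) + n + 2.0 * ridge_strength * n * w

    # projected gradient with Barzilai-Borwein steps and a nonmonotone
    # (last-10) Armijo safeguard; stationarity measured on the unit-scaled
    # projected gradient (the raw gradient is O(depth))
    w = np.full(T, 0.5 / T)
    f = objective(w)
    g = gradient(w)
    step = 1.0 / max(n, 1.0)
    recent = [f]
    converged = False
    for _ in range(cfg.max_iter):
        crit = np.abs(w - _project_capped_simplex(w - g / max(n, 1.0))).max()
        if crit < cfg.tol * 100:
            converged = True
            break
        f_ref = max(recent)
        while True:
            w_new = _project_capped_simplex(w - step * g)
            d = w_new - w
            f_new = objective(w_new)
            if f_new <= f_ref + g @ d + (d @ d) / (2 * step) + 1e-12 or step < 1e-18:
                break
            step *= 0.5
        g_new = gradient(w_new)
        dg = g_new - g
        denom = d @ dg
        step = float(np.clip((d @ d) / denom, 1e-12, 1e6)) if denom > 0 else step * 2.0
        w, f, g = w_new, f_new, g_new
        recent.append(f)
        if len(recent) > 10:
            recent.pop(0)
    if not converged:
        crit = np.abs(w - _project_capped_simplex(w - g / max(n, 1.0))).max()
        if crit > 1e-3:
            raise RuntimeError(f"weight fit did not converge (criterion {crit:.2e})")
    mu = np.maximum(theta.T @ w, 1e-300)
    loglik = float(y @ np.log(n * mu) - n * w.sum())
    return w, loglik


def prefilter_celltypes(y: np.ndarray, theta: np.ndarray, types: list[str],
                        depth: float, config: MappingConfig | None = None):
    """Candidate types for a bead: union of the supports (w > w_min) of the
    two ridge-penalized full fits plus the best single-type fits; the top-10
    list ranks candidates by singlet log-likelihood (ties by ridge weight)."""
    cfg = config or MappingConfig()
    T = len(types)
    ridge_w = np.zeros(T)
    support = set()
    for ridge in cfg.ridge_strengths:
        w, _ = fit_weights(y, theta, depth, ridge_strength=ridge, config=cfg)
        ridge_w = np.maximum(ridge_w, w)
        support |= set(np.flatnonzero(w > cfg.w_min).tolist())
    singlet_ll = np.array([
        fit_weights(y, theta[[t]], depth, config=cfg)[1] for t in range(T)
    ])
    singlet_rank = np.argsort(-singlet_ll, kind="stable")
    support |= set(singlet_rank[: cfg.n_top].tolist())
    candidates = sorted(support)
    if len(candidates) < 2:
        logger.info("prefilter found < 2 candidates; falling back to all types")
        candidates = list(range(T))
    order = sorted(candidates, key=lambda t: (-singlet_ll[t], -ridge_w[t], types[t]))
    top10 = order[: cfg.n_top]
    return ([types[t] for t in candidates], [types[t] for t in top10],
            {types[t]: float(singlet_ll[t]) for t in range(T)})


def score_pairs(y: np.ndarray, theta: np.ndarray, types: list[str],
                candidates: list[str], top10: list[str], depth: float,
                config: MappingConfig | None = None) -> pd.DataFrame:
    """Fit every admissible unordered pair (one member from the top-10 list,
    the other from the full candidate list) with ridge 0; sorted descending
    by log-likelihood."""
    cfg = config or MappingConfig()
    ti = {t: i for i, t in enumerate(types)}
    pairs = set()
    for a in top10:
        for b in candidates:
            if a != b:
                pairs.add(tuple(sorted((a, b))))
    for a, b in itertools.combinations(sorted(top10), 2):
        pairs.add((a, b))
    rows = []
    for a, b in sorted(pairs):
        try:
            w, ll = fit_weights(y, theta[[ti[a], ti[b]]], depth, config=cfg)
        except RuntimeError as exc:  # pragma: no cover - fit failure is rare
            logger.warning("pair (%s, %s) skipped: %s", a, b, exc)
            continue
        rows.append({"type_a": a, "type_b": b, "loglik": ll,
                     "w_a": float(w[0]), "w_b": float(w[1])})
    table = pd.DataFrame(rows).sort_values("loglik", ascending=False,
                                           ignore_index=True)
    return table


def confidence_scores(pair_table: pd.DataFrame,
                      config: MappingConfig | None = None):
    """Pair-frequency confidence: among pairs within the likelihood window
    of the best, a type's confidence is its occurrence count over twice the
    number of well-fitting pairs (so confidences sum to 1 and max at 0.5)."""
    cfg = config or MappingConfig()
    if pair_table.empty:
        raise ValueError("empty pair table")
    best = pair_table["loglik"].max()
    well = pair_table[pair_table["loglik"] >= best - cfg.likelihood_window]
    n_pairs = len(well)
    occ: dict[str, int] = {}
    for _, row in well.iterrows():
        occ[row["type_a"]] = occ.get(row["type_a"], 0) + 1
        occ[row["type_b"]] = occ.get(row["type_b"], 0) + 1
    conf = {t: c / (2 * n_pairs) for t, c in occ.items()}
    confident = {t for t, c in conf.items() if c > cfg.confidence_threshold}
    return conf, confident, well


def map_beads(beads: BeadMatrix, references: dict[str, ReferenceProfiles],
              config: MappingConfig | None = None,
              keep_pair_tables: bool = False) -> BeadMapping:
    """Filter -> prefilter -> pair scoring -> confidence for every bead,
    within its region's tailored reference."""
    cfg = config or MappingConfig()
    bead_rows, conf_rows, pair_tables = [], [], {}
    regions = beads.bead_meta["region"].values
    bead_ids = beads.bead_meta["bead_id"].values
    eligible_by_region = {}
    for region, ref in references.items():
        mask = regions == region
        if not mask.any():
            continue
        flags = filter_beads(beads, ref.tailored_genes, cfg)
        eligible_by_region[region] = mask & flags

    gi_cache = {}
    for region, ref in references.items():
        mask = regions == region
        if not mask.any():
            continue
        if region not in gi_cache:
            th_t, idx = ref.tailored_theta()
            # renormalize over the tailored gene space so proportions and
            # observed depths stay on the same scale
            row_mass = th_t.sum(axis=1, keepdims=True)
            gi_cache[region] = (th_t / row_mass, idx)
        th, idx = gi_cache[region]
        elig = eligible_by_region[region]
        for i in np.flatnonzero(mask):
            if not elig[i]:
                bead_rows.append({"bead_id": bead_ids[i], "region": region,
                                  "eligible": False})
                continue
            y = np.asarray(beads.counts[i, idx].todense()).ravel()
            depth = float(y.sum())
            cands, top10, _ = prefilter_celltypes(y, th, ref.types, depth, cfg)
            table = score_pairs(y, th, ref.types, cands, top10, depth, cfg)
            conf, confident, well = confidence_scores(table, cfg)
            best = table.iloc[0]
            bead_rows.append({
                "bead_id": bead_ids[i], "region": region, "eligible": True,
                "type_a": best["type_a"], "type_b": best["type_b"],
                "w_a": best["w_a"], "w_b": best["w_b"],
                "loglik": best["loglik"], "n_well_fitting": len(well),
            })
            for t, c in sorted(conf.items()):
                conf_rows.append({"bead_id": bead_ids[i], "region": region,
                                  "type": t, "confidence": c,
                                  "confident": t in confident})
            if keep_pair_tables:
                pair_tables[bead_ids[i]] = table
    unknown = ~np.isin(regions, list(references))
    for i in np.flatnonzero(unknown):
        bead_rows.append({"bead_id": bead_ids[i], "region": regions[i],
                          "eligible": False})
    beads_df = pd.DataFrame(bead_rows, columns=[
        "bead_id", "region", "eligible", "type_a", "type_b", "w_a", "w_b",
        "loglik", "n_well_fitting"])
    beads_df["eligible"] = beads_df["eligible"].astype(bool)
    conf_df = pd.DataFrame(conf_rows, columns=[
        "bead_id", "region", "type", "confidence", "confident"])
    conf_df = conf_df.astype({"confidence": float, "confident": bool})
    return BeadMapping(beads=beads_df, confidences=conf_df, pair_tables=pair_tables)
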