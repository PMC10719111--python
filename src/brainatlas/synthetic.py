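"""Ground-truth-labelled synthetic data for the atlas pipeline.

Emulates the statistical structure the downstream stages assume: clustered
snRNA-seq UMI counts with discrete marker genes and log-normal depth
(median ~5,000 UMIs/cell), spatial beads that are 1-2-cell-type mixtures
inside labelled regions, and a latent activity program that drives a module
of genes correlated with an immediate-early-gene anchor (a *Fos* stand-in).

All generation is multinomial at a fixed per-cell depth (conditionally
Poisson per gene), matching the binomial/Poisson sampling model the
variable-gene selection assumes. Optional negative-binomial overdispersion
is available behind a flag but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
import math

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import brentq

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "CellProfileMatrix",
    "BeadMatrix",
    "build_ground_truth",
    "simulate_cells",
    "simulate_beads",
    "simulate_pseudocell_matrix",
]

# canonical IEG names used for the activity module (anchor first)
DEFAULT_IEGS = ["Fos", "Junb", "Egr1", "Arc", "Fosb", "Npas4", "Nr4a1", "Btg2", "Dusp1"]

# gene-family prefixes used for QC metrics (configurable in GeneratorConfig)
MITO_PREFIX = "mt-"
RIBO_PREFIXES = ("Rps", "Rpl")
OXPHOS_PREFIX = "Ndufa"
LNC_PREFIX = "Gm"


@dataclass
class GeneratorConfig:
    """Settings for :func:`build_ground_truth`.

    ``marker_strength`` is the relative weight of a marker gene in its
    on-state (default 8e-4, i.e. an expected 4 counts at a depth of 5,000
    UMIs); ``marker_fold`` is the on-cell vs off-cell rate ratio within the
    marker's own type. Cross-type leakage is ``marker_strength / fold**2``:
    markers are effectively absent outside their type, which is the discrete
    regime the marker-based clustering termination test assumes.
    """

    n_types: int = 5
    n_genes: int = 200
    n_regions: int = 1
    n_markers_per_type: int = 3
    marker_fold: float = 20.0
    marker_on_fraction: float = 0.9
    marker_strength: float = 8e-4
    doublet_rate: float = 0.0
    type_proportions: tuple[float, ...] | None = None
    share_markers: bool = False
    region_overlap: bool = False
    # hierarchy: types are grouped into classes carrying their own markers
    # (shared by every type of the class), like neuronal-class markers
    n_classes: int = 2
    n_class_markers: int = 3
    # mild per-type baseline jitter: types differ globally, not only in
    # their discrete markers (log-normal factor per type x gene)
    type_jitter_sigma: float = 0.4
    # continuous per-cell state program shared across types: keeps the
    # expression manifold connected, as cell state does in real tissue
    n_state_genes: int = 40
    state_sigma: float = 0.7
    # activity program: list of (gene_name, target_pearson_r); anchor is the
    # first DEFAULT_IEGS entry. Empty list disables the program.
    activity_targets: tuple[tuple[str, float], ...] = ()
    activity_anchor_beta: float = 3.0
    ieg_strength: float = 2e-3  # relative weight of anchor/module genes
    n_mito: int = 5
    n_ribo: int = 8
    n_oxphos: int = 8
    n_lnc: int = 5
    # total expression mass per QC gene family (shared by all types, so the
    # hard mito filter and the quality network see only sampling noise)
    mito_mass: float = 0.003
    ribo_mass: float = 0.03
    oxphos_mass: float = 0.02
    lnc_mass: float = 0.01
    overdispersion: float = 0.0  # NB dispersion; 0 = pure multinomial
    depth_reference: float = 5000.0
    seed: int = 0


@dataclass
class GroundTruth:
    """Generative truth: type tree, per-type expression profiles, marker
    table, region compositions and the activity-module specification."""

    type_hierarchy: dict
    type_ids: list[str]
    gene_ids: list[str]
    type_profiles: np.ndarray  # types x genes, rows sum to 1
    marker_table: dict  # type -> list of (gene, on_fraction, fold)
    type_proportions: np.ndarray
    doublet_rate: float
    region_ids: list[str]
    region_composition: np.ndarray  # regions x types, rows sum to 1
    activity_spec: dict  # anchor, members [(gene, r, beta)], participation
    seed: int
    config: GeneratorConfig
    type_class: dict = field(default_factory=dict)  # type id -> class id
    class_marker_table: dict = field(default_factory=dict)  # class -> [(gene, on_frac, fold)]
    state_loadings: dict = field(default_factory=dict)  # gene -> loading

    def gene_index(self, gene: str) -> int:
        lut = getattr(self, "_gene_lut", None)
        if lut is None:
            lut = {g: i for i, g in enumerate(self.gene_ids)}
            object.__setattr__(self, "_gene_lut", lut)
        return lut[gene]

    def to_json(self, path) -> None:
        payload = {
            "type_hierarchy": self.type_hierarchy,
            "type_ids": self.type_ids,
            "gene_ids": self.gene_ids,
            "type_profiles": self.type_profiles.tolist(),
            "marker_table": self.marker_table,
            "type_proportions": self.type_proportions.tolist(),
            "doublet_rate": self.doublet_rate,
            "region_ids": self.region_ids,
            "region_composition": self.region_composition.tolist(),
            "activity_spec": self.activity_spec,
            "seed": self.seed,
            "config": asdict(self.config),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


@dataclass
class CellProfileMatrix:
    """Sparse cells x genes UMI counts plus per-cell metadata."""

    counts: sp.csr_matrix
    cell_meta: pd.DataFrame  # library, donor, region, truth_type, truth_doublet, truth_activity
    gene_ids: list[str]

    def __post_init__(self):
        if self.counts.shape[0] != len(self.cell_meta):
            raise ValueError("cell_meta row count must equal counts row count")
        if self.counts.shape[1] != len(self.gene_ids):
            raise ValueError("gene_ids length must equal counts column count")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def depths(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def subset(self, cell_mask) -> "CellProfileMatrix":
        idx = np.asarray(cell_mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CellProfileMatrix(
            counts=self.counts[idx],
            cell_meta=self.cell_meta.iloc[idx].reset_index(drop=True),
            gene_ids=self.gene_ids,
        )


@dataclass
class BeadMatrix:
    """Beads x genes counts with coordinates, region labels and (optionally)
    the true cell-type composition of each bead."""

    counts: sp.csr_matrix
    bead_meta: pd.DataFrame  # bead_id, x, y, region, truth_composition
    gene_ids: list[str]

    def __post_init__(self):
        if self.counts.shape[0] != len(self.bead_meta):
            raise ValueError("bead_meta row count must equal counts row count")

    @property
    def n_beads(self) -> int:
        return self.counts.shape[0]

    def depths(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()


def _activity_beta_for_r(target_r: float, lam_gene: float, lam_anchor: float,
                         beta_anchor: float) -> float:
    """Solve for the gene's activity slope giving the target Pearson r.

    Counts are Poisson(lam*(1+beta*a)) with a ~ U(0,1) shared per cell, so
    cov = lam_g*lam_a*b_g*b_a/12 and var = lam*(1+beta/2) + lam^2 beta^2/12;
    r is monotone in beta and capped below 1 by the anchor's own noise.
    """
    var_a = lam_anchor * (1 + beta_anchor / 2) + lam_anchor**2 * beta_anchor**2 / 12

    def r_of(beta):
        cov = lam_gene * lam_anchor * beta * beta_anchor / 12.0
        var_g = lam_gene * (1 + beta / 2) + lam_gene**2 * beta**2 / 12
        return cov / math.sqrt(var_g * var_a)

    r_max = r_of(1e6)
    if target_r >= r_max:
        raise ValueError(
            f"target r={target_r:.3f} unreachable (max {r_max:.3f}) at "
            f"lam_gene={lam_gene:.3g}; raise ieg_strength or anchor beta"
        )
    return brentq(lambda b: r_of(b) - target_r, 1e-9, 1e6)


def build_ground_truth(config: GeneratorConfig) -> GroundTruth:
    """Construct the generative truth object for a configuration.

    Deterministic for a fixed seed. Marker genes are disjoint across types
    unless ``share_markers``; activity-module genes are never markers.
    """
    cfg = config
    if cfg.n_types < 2:
        raise ValueError("need at least 2 types")
    if cfg.n_genes < 50:
        raise ValueError("need at least 50 genes")
    if cfg.n_regions < 1:
        raise ValueError("need at least 1 region")
    if not (0 <= cfg.doublet_rate < 0.5):
        raise ValueError("doublet_rate must be in [0, 0.5)")

    rng = np.random.default_rng(cfg.seed)

    activity_genes = [g for g, _ in cfg.activity_targets]
    anchor = DEFAULT_IEGS[0]
    special = [anchor] + [g for g in activity_genes if g != anchor]
    family = (
        [f"{MITO_PREFIX}Nd{i+1}" for i in range(cfg.n_mito)]
        + [f"{RIBO_PREFIXES[i % 2]}{10 + i}" for i in range(cfg.n_ribo)]
        + [f"{OXPHOS_PREFIX}{i+1}" for i in range(cfg.n_oxphos)]
        + [f"{LNC_PREFIX}{20000 + i}" for i in range(cfg.n_lnc)]
    )
    n_classes = max(1, min(cfg.n_classes, cfg.n_types))
    n_markers = cfg.n_types * cfg.n_markers_per_type
    n_cls_markers = n_classes * cfg.n_class_markers if n_classes > 1 else 0
    marker_names = [
        f"Mk{t:02d}_{m}" for t in range(cfg.n_types) for m in range(cfg.n_markers_per_type)
    ]
    class_marker_names = [
        f"Ck{c}_{m}" for c in range(n_classes) for m in range(cfg.n_class_markers)
    ] if n_classes > 1 else []
    n_named = len(special) + len(family) + n_markers + n_cls_markers
    if n_named > cfg.n_genes:
        raise ValueError(
            f"markers + named genes ({n_named}) exceed gene universe ({cfg.n_genes})"
        )
    n_bg = cfg.n_genes - n_named
    bg = [f"Gene{i:04d}" for i in range(n_bg)]
    gene_ids = special + family + marker_names + class_marker_names + bg

    # shared baseline: IEG and marker genes pinned at fixed simplex weights,
    # everything else shares the remainder with log-normal weights (a few
    # genes dominate, like real data)
    gi = {g: i for i, g in enumerate(gene_ids)}
    leak = cfg.marker_strength / cfg.marker_fold**2
    families = {
        MITO_PREFIX: cfg.mito_mass, "ribo": cfg.ribo_mass,
        OXPHOS_PREFIX: cfg.oxphos_mass, LNC_PREFIX: cfg.lnc_mass,
    }
    family_genes = [g for g in family]
    pinned = set(special) | set(marker_names) | set(class_marker_names) \
        | set(family_genes)
    pinned_mass = (cfg.ieg_strength * len(special)
                   + leak * (n_markers + n_cls_markers)
                   + sum(families.values()))
    if pinned_mass >= 0.5:
        raise ValueError("pinned IEG/marker/family mass too large for the gene universe")
    base = np.zeros(cfg.n_genes)
    free_idx = np.array([gi[g] for g in gene_ids if g not in pinned])
    w = rng.lognormal(mean=0.0, sigma=1.0, size=free_idx.size)
    base[free_idx] = w / w.sum() * (1.0 - pinned_mass)
    for g in special:
        base[gi[g]] = cfg.ieg_strength
    for name in marker_names + class_marker_names:
        base[gi[name]] = leak
    # QC family masses fixed across types, lognormal within the family
    for prefix, mass in families.items():
        if prefix == "ribo":
            members = [g for g in family_genes if g.startswith(RIBO_PREFIXES)]
        else:
            members = [g for g in family_genes if g.startswith(prefix)]
        if members:
            fw = rng.lognormal(0.0, 0.5, size=len(members))
            fw = fw / fw.sum() * mass
            for g, wt in zip(members, fw):
                base[gi[g]] = wt

    type_ids = [f"T{t:02d}" for t in range(cfg.n_types)]
    class_ids = [f"C{c}" for c in range(n_classes)]
    type_class = {type_ids[t]: class_ids[t % n_classes] for t in range(cfg.n_types)}

    profiles = np.tile(base, (cfg.n_types, 1))
    if cfg.type_jitter_sigma > 0:
        jitter = rng.lognormal(0.0, cfg.type_jitter_sigma, size=profiles.shape)
        jitter[:, [gi[g] for g in pinned]] = 1.0  # jitter only free genes
        profiles = profiles * jitter
    marker_table: dict[str, list] = {t: [] for t in type_ids}
    class_marker_table: dict[str, list] = {c: [] for c in class_ids}
    for t in range(cfg.n_types):
        for m in range(cfg.n_markers_per_type):
            if cfg.share_markers and t > 0 and m == 0:
                gene = f"Mk{t-1:02d}_0"  # first marker shared with previous type
            else:
                gene = f"Mk{t:02d}_{m}"
            profiles[t, gi[gene]] = cfg.marker_strength
            marker_table[type_ids[t]].append(
                (gene, float(cfg.marker_on_fraction), float(cfg.marker_fold))
            )
    if n_classes > 1:
        for c in range(n_classes):
            for m in range(cfg.n_class_markers):
                gene = f"Ck{c}_{m}"
                for t in range(cfg.n_types):
                    if type_class[type_ids[t]] == class_ids[c]:
                        profiles[t, gi[gene]] = cfg.marker_strength
                class_marker_table[class_ids[c]].append(
                    (gene, float(cfg.marker_on_fraction), float(cfg.marker_fold))
                )
    profiles = profiles / profiles.sum(axis=1, keepdims=True)

    # continuous state program over background genes (never markers/IEGs/QC)
    state_loadings: dict[str, float] = {}
    if cfg.n_state_genes > 0 and cfg.state_sigma > 0:
        pool = [g for g in bg][: cfg.n_state_genes]
        for g in pool:
            state_loadings[g] = float(cfg.state_sigma * rng.standard_normal())

    if cfg.type_proportions is not None:
        props = np.asarray(cfg.type_proportions, dtype=float)
        if len(props) != cfg.n_types:
            raise ValueError("type_proportions length mismatch")
        props = props / props.sum()
    else:
        props = np.full(cfg.n_types, 1.0 / cfg.n_types)

    region_ids = [f"R{r}" for r in range(cfg.n_regions)]
    comp = np.zeros((cfg.n_regions, cfg.n_types))
    if cfg.n_regions == 1:
        comp[0] = props
    else:
        # contiguous blocks of types per region (so regions cut across the
        # class structure); overlapping regions share every type at
        # Dirichlet weights instead
        if cfg.region_overlap:
            comp = rng.dirichlet(np.ones(cfg.n_types), size=cfg.n_regions)
        else:
            block = math.ceil(cfg.n_types / cfg.n_regions)
            for t in range(cfg.n_types):
                comp[min(t // block, cfg.n_regions - 1), t] = props[t]
            comp = comp / comp.sum(axis=1, keepdims=True)

    # per-gene activity slopes solved from the target correlations
    lam_ref = cfg.ieg_strength * cfg.depth_reference
    members = []
    for gene, r in cfg.activity_targets:
        if gene == anchor:
            continue
        beta = _activity_beta_for_r(r, lam_ref, lam_ref, cfg.activity_anchor_beta)
        members.append([gene, float(r), float(beta)])
    activity_spec = {
        "anchor": anchor,
        "anchor_beta": float(cfg.activity_anchor_beta) if cfg.activity_targets else 0.0,
        "members": members,
        "participating_types": list(type_ids),
    }

    if n_classes > 1:
        hierarchy = {
            "id": "root",
            "children": [
                {
                    "id": c,
                    "children": [
                        {"id": t, "children": []} for t in type_ids if type_class[t] == c
                    ],
                }
                for c in class_ids
            ],
        }
    else:
        hierarchy = {"id": "root",
                     "children": [{"id": t, "children": []} for t in type_ids]}
    return GroundTruth(
        type_hierarchy=hierarchy,
        type_ids=type_ids,
        gene_ids=gene_ids,
        type_profiles=profiles,
        marker_table=marker_table,
        type_proportions=props,
        doublet_rate=cfg.doublet_rate,
        region_ids=region_ids,
        region_composition=comp,
        activity_spec=activity_spec,
        seed=cfg.seed,
        config=cfg,
        type_class=type_class,
        class_marker_table=class_marker_table,
        state_loadings=state_loadings,
    )


def _draw_depths(rng, n: int, median: float) -> np.ndarray:
    """Log-normal depths with sigma=0.5 parameterized by the median;
    zero-depth draws are resampled."""
    d = np.rint(rng.lognormal(mean=np.log(median), sigma=0.5, size=n)).astype(np.int64)
    while (zero := d == 0).any():
        d[zero] = np.rint(
            rng.lognormal(mean=np.log(median), sigma=0.5, size=int(zero.sum()))
        ).astype(np.int64)
    return d


def _cell_rate(truth: GroundTruth, type_idx, rng, activity: float,
               state: float = 0.0, weights=(0.5, 0.5)) -> np.ndarray:
    """Expression rate vector for one cell: type profile (or weighted doublet
    mix), per-marker on/off Bernoulli (type and class markers), continuous
    state modulation and activity-module scaling; re-normalized."""
    gi = truth.gene_index
    if isinstance(type_idx, tuple):
        rate = (weights[0] * truth.type_profiles[type_idx[0]]
                + weights[1] * truth.type_profiles[type_idx[1]])
        own = [truth.type_ids[type_idx[0]], truth.type_ids[type_idx[1]]]
    else:
        rate = truth.type_profiles[type_idx].copy()
        own = [truth.type_ids[type_idx]]
    markers = []
    for t in own:
        markers.extend(truth.marker_table[t])
        cls = truth.type_class.get(t)
        if cls is not None and truth.class_marker_table.get(cls):
            markers.extend(truth.class_marker_table[cls])
    for gene, on_frac, fold in markers:
        if rng.random() >= on_frac:
            rate[gi(gene)] /= fold
    # mean-preserving log-normal state factor per state gene
    for gene, s in truth.state_loadings.items():
        rate[gi(gene)] *= math.exp(s * state - 0.5 * s * s)
    spec = truth.activity_spec
    if spec["members"] or spec["anchor_beta"] > 0:
        if any(t in spec["participating_types"] for t in own):
            rate[gi(spec["anchor"])] *= 1 + spec["anchor_beta"] * activity
            for gene, _r, beta in spec["members"]:
                rate[gi(gene)] *= 1 + beta * activity
    return rate / rate.sum()


def simulate_cells(truth: GroundTruth, n_cells: int, depth_median: float,
                   seed: int, n_libraries: int = 2, n_donors: int = 2) -> CellProfileMatrix:
    """Draw labelled cells: type (or doublet pair), log-normal depth,
    multinomial counts, with truth labels recorded in ``cell_meta``."""
    if n_cells < 10 * len(truth.type_ids):
        raise ValueError("n_cells must be at least 10x the number of types")
    rng = np.random.default_rng(seed)
    k = len(truth.type_ids)

    depths = _draw_depths(rng, n_cells, depth_median)
    types = rng.choice(k, size=n_cells, p=truth.type_proportions)
    is_doublet = rng.random(n_cells) < truth.doublet_rate
    activity = rng.random(n_cells)
    state = rng.standard_normal(n_cells)

    # region tag per cell: draw a region consistent with the type's presence
    comp = truth.region_composition  # regions x types
    rows, cols, vals = [], [], []
    meta_type, meta_region = [], []
    for i in range(n_cells):
        t = int(types[i])
        if is_doublet[i]:
            others = [j for j in range(k) if j != t]
            t2 = int(rng.choice(others))
            rate = _cell_rate(truth, (t, t2), rng, activity[i], state[i])
            meta_type.append(f"{truth.type_ids[t]}+{truth.type_ids[t2]}")
        else:
            rate = _cell_rate(truth, t, rng, activity[i], state[i])
            meta_type.append(truth.type_ids[t])
        pr = comp[:, t]
        pr = pr / pr.sum() if pr.sum() > 0 else np.full(comp.shape[0], 1 / comp.shape[0])
        meta_region.append(truth.region_ids[int(rng.choice(comp.shape[0], p=pr))])
        if truth.config.overdispersion > 0:
            # gamma-perturbed rates give NB marginals at fixed depth
            shape = 1.0 / truth.config.overdispersion
            rate = rate * rng.gamma(shape, 1.0 / shape, size=rate.size)
            rate = rate / rate.sum()
        cnt = rng.multinomial(depths[i], rate)
        nz = np.flatnonzero(cnt)
        rows.extend([i] * len(nz))
        cols.extend(nz.tolist())
        vals.extend(cnt[nz].tolist())

    counts = sp.csr_matrix(
        (vals, (rows, cols)), shape=(n_cells, len(truth.gene_ids)), dtype=np.int64
    )
    singlet_types = np.where(is_doublet, "", np.array(truth.type_ids)[types])
    meta = pd.DataFrame(
        {
            "cell_id": [f"cell{i:06d}" for i in range(n_cells)],
            "library": [f"lib{i % n_libraries}" for i in range(n_cells)],
            "donor": [f"donor{i % n_donors}" for i in range(n_cells)],
            "region": meta_region,
            "truth_type": meta_type,
            "truth_singlet_type": singlet_types,
            "truth_doublet": is_doublet,
            "truth_activity": activity,
            "truth_state": state,
        }
    )
    out = CellProfileMatrix(counts=counts, cell_meta=meta, gene_ids=list(truth.gene_ids))
    if n_cells >= 50 * k:
        seen = set(meta.loc[~meta.truth_doublet, "truth_type"])
        missing = [t for t in truth.type_ids if t not in seen]
        if missing:
            raise RuntimeError(f"types received no cells: {missing}")
    return out


def simulate_beads(truth: GroundTruth, n_beads: int, depth_median: float,
                   doublet_fraction: float, seed: int) -> BeadMatrix:
    """Spatial beads: each bead gets a region, one type (singlet) or a
    Dirichlet(1,1)-weighted pair (doublet) from that region's composition,
    and multinomial counts at a log-normal depth."""
    if not 0 <= doublet_fraction <= 1:
        raise ValueError("doublet_fraction must be in [0,1]")
    comp = truth.region_composition
    if (comp.sum(axis=1) == 0).any():
        raise ValueError("a region has an empty composition")
    rng = np.random.default_rng(seed)
    n_regions, k = comp.shape

    depths = _draw_depths(rng, n_beads, depth_median)
    regions = rng.choice(n_regions, size=n_beads)
    rows, cols, vals = [], [], []
    meta_rows = []
    for i in range(n_beads):
        r = int(regions[i])
        p = comp[r] / comp[r].sum()
        support = np.flatnonzero(p)
        if rng.random() < doublet_fraction and support.size >= 2:
            t1 = int(rng.choice(k, p=p))
            p2 = p.copy()
            p2[t1] = 0.0
            t2 = int(rng.choice(k, p=p2 / p2.sum()))
            w = rng.dirichlet([1.0, 1.0])
            rate = _cell_rate(truth, (t1, t2), rng, rng.random(),
                              rng.standard_normal(), weights=(w[0], w[1]))
            composition = [
                (truth.type_ids[t1], float(w[0])),
                (truth.type_ids[t2], float(w[1])),
            ]
        else:
            t1 = int(rng.choice(k, p=p))
            rate = _cell_rate(truth, t1, rng, rng.random(), rng.standard_normal())
            composition = [(truth.type_ids[t1], 1.0)]
        cnt = rng.multinomial(depths[i], rate / rate.sum())
        nz = np.flatnonzero(cnt)
        rows.extend([i] * len(nz))
        cols.extend(nz.tolist())
        vals.extend(cnt[nz].tolist())
        meta_rows.append(
            {
                "bead_id": f"bead{i:06d}",
                "x": float(rng.uniform(0, 3000.0)),
                "y": float(rng.uniform(0, 3000.0)),
                "region": truth.region_ids[r],
                "truth_composition": json.dumps(composition),
            }
        )
    counts = sp.csr_matrix(
        (vals, (rows, cols)), shape=(n_beads, len(truth.gene_ids)), dtype=np.int64
    )
    return BeadMatrix(counts=counts, bead_meta=pd.DataFrame(meta_rows),
                      gene_ids=list(truth.gene_ids))


def simulate_pseudocell_matrix(n_pseudocells: int, n_genes: int,
                               module: dict[str, float], anchor: str,
                               seed: int, gene_prefix: str = "Gene"):
    """Synthetic normalized pseudocell matrix with a planted anchor-correlated
    module (Gaussian, unit scale) — a direct fixture for the ARG criteria.

    ``module`` maps gene name -> target Pearson r with the anchor. Returns
    (DataFrame pseudocells x genes, gene list).
    """
    rng = np.random.default_rng(seed)
    genes = [anchor] + list(module) + [
        f"{gene_prefix}{i:04d}" for i in range(n_genes - 1 - len(module))
    ]
    z = rng.standard_normal(n_pseudocells)
    mat = rng.standard_normal((n_pseudocells, len(genes)))
    mat[:, 0] = z
    for j, (g, r) in enumerate(module.items(), start=1):
        mat[:, j] = r * z + math.sqrt(1 - r * r) * rng.standard_normal(n_pseudocells)
    return pd.DataFrame(mat, columns=genes)
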