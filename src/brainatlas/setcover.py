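"""Minimal combinatorial marker panels by exact set cover.

For a target cell type, the universe is every other type; a gene that is
"on" in the target (nonzero fraction >= tau_on) covers another type exactly
when it is "off" there (nonzero fraction <= tau_off). The smallest gene
subset covering the universe is the minimal conjunctive marker panel: all
selected genes on identifies the target uniquely. Solved to optimality as
an integer program (HiGHS via scipy); a greedy fallback is available behind
an explicit flag and marked non-optimal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import LinearConstraint, milp
from scipy.stats import fisher_exact

__all__ = [
    "BinarizedExpression",
    "MarkerCover",
    "binarize_expression",
    "minimal_marker_set",
    "marker_covers",
    "family_enrichment",
]


@dataclass
class BinarizedExpression:
    """On/off calls per (type, gene); fractions in between are neither."""

    types: list
    genes: list
    on: np.ndarray  # bool, types x genes
    off: np.ndarray
    tau_on: float
    tau_off: float


@dataclass
class MarkerCover:
    """Per-type minimal marker panel with a distinguishing certificate."""

    target: str
    genes: list
    size: int
    feasible: bool
    certificate: dict  # other type -> selected gene that is off there
    optimal: bool = True


def binarize_expression(fractions: pd.DataFrame, tau_on: float = 0.5,
                        tau_off: float = 0.1) -> BinarizedExpression:
    """Threshold a type x gene nonzero-fraction table into on/off calls."""
    if not (0 <= tau_off < tau_on <= 1):
        raise ValueError("need 0 <= tau_off < tau_on <= 1")
    vals = fractions.values.astype(float)
    return BinarizedExpression(
        types=list(fractions.index),
        genes=list(fractions.columns),
        on=vals >= tau_on,
        off=vals <= tau_off,
        tau_on=tau_on,
        tau_off=tau_off,
    )


def _solve_cover_milp(cover: np.ndarray, weights: np.ndarray) -> np.ndarray | None:
    """Minimize sum(x) (with a tiny tie-break on weights) subject to
    cover @ x >= 1 per universe row, x binary. Returns selected columns."""
    n = cover.shape[1]
    # tie-break: prefer larger weight, then earlier column; epsilon small
    # enough that cardinality always dominates
    wmax = max(weights.max(), 1.0)
    eps = 1e-6 / (n * wmax)
    c = 1.0 - eps * weights - (eps * 1e-3) * (n - np.arange(n)) / n
    constraint = LinearConstraint(cover.astype(float), lb=1.0)
    res = milp(c=c, integrality=np.ones(n), bounds=(0, 1),
               constraints=[constraint])
    if not res.success:
        return None
    return np.flatnonzero(np.round(res.x) > 0)


def minimal_marker_set(target, binarized: BinarizedExpression,
                       max_size: int = 8, margins: np.ndarray | None = None,
                       greedy: bool = False) -> MarkerCover:
    """Minimum-cardinality panel of target-on genes covering all other types.

    Ties are broken toward genes with larger ``margins`` (summed
    nonzero-fraction margin), then by gene order. ``greedy=True`` replaces
    the exact solve with the standard greedy heuristic (marked non-optimal).
    """
    ti = binarized.types.index(target)
    on_genes = np.flatnonzero(binarized.on[ti])
    others = [i for i in range(len(binarized.types)) if i != ti]
    if on_genes.size == 0 or not others:
        return MarkerCover(target=target, genes=[], size=0,
                           feasible=not others, certificate={})
    # cover[u, j] = gene on_genes[j] is off in other-type u
    cover = binarized.off[np.ix_(others, on_genes)]
    coverable = cover.any(axis=1)
    if not coverable.all():
        return MarkerCover(target=target, genes=[], size=0, feasible=False,
                           certificate={})
    w = (margins[on_genes] if margins is not None
         else np.zeros(on_genes.size))
    if greedy:
        sel = _greedy_cover(cover, w)
        optimal = False
    else:
        sel = _solve_cover_milp(cover, w)
        optimal = True
        if sel is None:
            return MarkerCover(target=target, genes=[], size=0, feasible=False,
                               certificate={})
    if sel.size > max_size:
        return MarkerCover(target=target, genes=[], size=int(sel.size),
                           feasible=False, certificate={}, optimal=optimal)
    genes = [binarized.genes[on_genes[j]] for j in sel]
    certificate = {}
    for row, u in enumerate(others):
        j = next(int(jj) for jj in sel if cover[row, jj])
        certificate[binarized.types[u]] = binarized.genes[on_genes[j]]
    return MarkerCover(target=target, genes=genes, size=len(genes),
                       feasible=True, certificate=certificate, optimal=optimal)


def _greedy_cover(cover: np.ndarray, weights: np.ndarray) -> np.ndarray:
    uncovered = np.ones(cover.shape[0], dtype=bool)
    chosen = []
    while uncovered.any():
        gains = cover[uncovered].sum(axis=0).astype(float)
        gains[chosen] = -1
        best = int(np.lexsort((-weights, -gains))[0])
        if gains[best] <= 0:
            break
        chosen.append(best)
        uncovered &= ~cover[:, best]
    return np.asarray(sorted(chosen), dtype=int)


def marker_covers(fractions: pd.DataFrame, tau_on: float = 0.5,
                  tau_off: float = 0.1, max_size: int = 8,
                  greedy: bool = False) -> dict[str, MarkerCover]:
    """Solve the cover for every type of a nonzero-fraction table.

    The tie-break margin of a gene for a target is its fraction there minus
    the mean fraction across the other types.
    """
    binar = binarize_expression(fractions, tau_on, tau_off)
    out = {}
    vals = fractions.values.astype(float)
    for i, t in enumerate(binar.types):
        others = [j for j in range(len(binar.types)) if j != i]
        margins = vals[i] - vals[others].mean(axis=0)
        out[t] = minimal_marker_set(t, binar, max_size=max_size,
                                    margins=margins, greedy=greedy)
    return out


def family_enrichment(covers: dict[str, MarkerCover], families: dict[str, str],
                      universe: list[str]) -> pd.DataFrame:
    """Fisher's exact (one-sided, enrichment) per gene family on the 2x2
    table of family membership among selected vs unselected genes; the odds
    ratio is the sample cross-product ratio."""
    if not families:
        raise ValueError("families must be non-empty")
    selected = sorted({g for c in covers.values() if c.feasible for g in c.genes})
    rows = []
    fam_names = sorted(set(families.values()))
    uni = set(universe)
    sel = set(selected)
    if not sel:
        return pd.DataFrame(columns=["family", "odds_ratio", "p", "a", "b", "c", "d"])
    for fam in fam_names:
        members = {g for g, f in families.items() if f == fam} & uni
        if not members:
            warnings.warn(f"family {fam!r} absent from the gene universe; skipped")
            continue
        a = len(sel & members)
        b = len(sel - members)
        c = len(members - sel)
        d = len(uni - sel - members)
        if b == 0 and c == 0:
            rows.append({"family": fam, "odds_ratio": np.inf, "p": np.nan,
                         "a": a, "b": b, "c": c, "d": d})
            continue
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        p = fisher_exact([[a, b], [c, d]], alternative="greater").pvalue
        rows.append({"family": fam, "odds_ratio": odds, "p": p,
                     "a": a, "b": b, "c": c, "d": d})
    return pd.DataFrame(rows)
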