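"""Rule-based neurotransmitter / neuropeptide assignment and regional
excitatory-inhibitory composition.

A cell type acquires a neurotransmitter identity when the fraction of its
cells with nonzero counts of the identity's essential genes reaches the nz
threshold (0.35): VGLUT1 Slc17a7, VGLUT2 Slc17a6, VGLUT3 Slc17a8, GABA
(Gad1|Gad2) & Slc32a1, GLY (Gad1|Gad2) & (Slc6a5|Slc6a9), CHOL Slc18a3 &
Chat, DOP Slc6a3, NOR Pnmt|Dbh, SER Slc6a4|Tph2. Neuropeptide ligands need
nonzero fraction >= 0.3 and mean >= 0.5 counts/cell (Oxt, Avp, Pmch, Agrp:
0.8 and 5 because of their cross-type contamination); receptors need 0.2
and 0.5. Dual glutamatergic/GABAergic types count as inhibitory in the
regional E/I fractions, which carry exact (Clopper-Pearson) binomial 95%
confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

__all__ = [
    "NeurochemRules",
    "CellTypeChemistry",
    "assign_neurotransmitters",
    "assign_neuropeptides",
    "clopper_pearson",
    "region_ei_fraction",
    "NT_RULES",
    "SPECIAL_NPS",
]

# identity -> list of clauses; each clause is a list of alternative genes
# (OR within a clause, AND across clauses)
NT_RULES: dict[str, list[list[str]]] = {
    "VGLUT1": [["Slc17a7"]],
    "VGLUT2": [["Slc17a6"]],
    "VGLUT3": [["Slc17a8"]],
    "GABA": [["Gad1", "Gad2"], ["Slc32a1"]],
    "GLY": [["Gad1", "Gad2"], ["Slc6a5", "Slc6a9"]],
    "CHOL": [["Slc18a3"], ["Chat"]],
    "DOP": [["Slc6a3"]],
    "NOR": [["Pnmt", "Dbh"]],
    "SER": [["Slc6a4", "Tph2"]],
}
EXCITATORY = {"VGLUT1", "VGLUT2", "VGLUT3"}
INHIBITORY = {"GABA", "GLY"}
SPECIAL_NPS = ("Oxt", "Avp", "Pmch", "Agrp")


@dataclass
class NeurochemRules:
    nz: float = 0.35
    np_frac: float = 0.3
    np_mean: float = 0.5
    special_nps: tuple = SPECIAL_NPS
    special_frac: float = 0.8
    special_mean: float = 5.0
    npr_frac: float = 0.2
    npr_mean: float = 0.5
    nt_rules: dict = field(default_factory=lambda: dict(NT_RULES))


@dataclass
class CellTypeChemistry:
    table: pd.DataFrame  # index: type; columns: nt (frozenset), ei_class, unresolved, np_ligands, nprs


def _rule_satisfied(clauses, fractions_row, nz) -> bool:
    return all(any(fractions_row.get(g, 0.0) >= nz for g in clause)
               for clause in clauses)


def assign_neurotransmitters(fractions: pd.DataFrame,
                             rules: NeurochemRules | None = None) -> CellTypeChemistry:
    """Multi-label neurotransmitter assignment from a type x gene
    nonzero-fraction table; types satisfying no rule are flagged unresolved."""
    rules = rules or NeurochemRules()
    needed = {g for clauses in rules.nt_rules.values() for c in clauses for g in c}
    missing = sorted(needed - set(fractions.columns))
    if missing:
        raise ValueError(f"fraction table lacks rule genes: {missing}")
    rows = []
    for t, row in fractions.iterrows():
        nts = {ident for ident, clauses in rules.nt_rules.items()
               if _rule_satisfied(clauses, row, rules.nz)}
        if nts & INHIBITORY:
            ei = "inhibitory"
        elif nts & EXCITATORY:
            ei = "excitatory"
        else:
            ei = "neither"
        rows.append({"type": t, "nt": frozenset(nts), "ei_class": ei,
                     "unresolved": len(nts) == 0,
                     "np_ligands": frozenset(), "nprs": frozenset()})
    return CellTypeChemistry(pd.DataFrame(rows).set_index("type"))


def assign_neuropeptides(fractions: pd.DataFrame, means: pd.DataFrame,
                         np_genes: list[str], npr_genes: list[str],
                         rules: NeurochemRules | None = None,
                         chemistry: CellTypeChemistry | None = None) -> CellTypeChemistry:
    """Neuropeptide-ligand and receptor labels from nonzero fractions and
    mean raw counts per cell.

    Ordinary ligands need fraction >= 0.3 and mean >= 0.5; the four
    high-contamination ligands need 0.8 and 5; receptors need 0.2 and 0.5.
    """
    rules = rules or NeurochemRules()
    rows = []
    for t in fractions.index:
        ligands = set()
        for g in np_genes:
            if g not in fractions.columns:
                continue
            if g in rules.special_nps:
                fmin, mmin = rules.special_frac, rules.special_mean
            else:
                fmin, mmin = rules.np_frac, rules.np_mean
            if fractions.at[t, g] >= fmin and means.at[t, g] >= mmin:
                ligands.add(g)
        nprs = {g for g in npr_genes if g in fractions.columns
                and fractions.at[t, g] >= rules.npr_frac
                and means.at[t, g] >= rules.npr_mean}
        rows.append({"type": t, "np_ligands": frozenset(ligands),
                     "nprs": frozenset(nprs)})
    np_table = pd.DataFrame(rows).set_index("type")
    if chemistry is not None:
        table = chemistry.table.copy()
        table["np_ligands"] = np_table["np_ligands"]
        table["nprs"] = np_table["nprs"]
        return CellTypeChemistry(table)
    np_table["nt"] = [frozenset()] * len(np_table)
    np_table["ei_class"] = "neither"
    np_table["unresolved"] = True
    return CellTypeChemistry(np_table)


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval."""
    if n == 0:
        return (0.0, 1.0)
    alpha = 1 - conf
    lo = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def region_ei_fraction(mapping, chemistry: CellTypeChemistry,
                       min_total: int = 5, conf: float = 0.95) -> pd.DataFrame:
    """Per-region inhibitory fraction #I/(#I+#E) over confidently mapped
    beads whose E/I type is in the bead's best (top-two) pair, with exact
    binomial confidence intervals; regions under ``min_total`` counted beads
    are flagged excluded."""
    table = chemistry.table
    ei_of = table["ei_class"].to_dict()
    conf_df = mapping.confidences
    best_pair = mapping.beads.set_index("bead_id")[["type_a", "type_b"]]
    rows = []
    counted = conf_df[conf_df["confident"]].merge(
        best_pair, left_on="bead_id", right_index=True, how="left")
    in_top2 = counted[(counted["type"] == counted["type_a"])
                      | (counted["type"] == counted["type_b"])]
    for region, grp in in_top2.groupby("region"):
        classes = grp["type"].map(ei_of)
        n_i = int((classes == "inhibitory").sum())
        n_e = int((classes == "excitatory").sum())
        total = n_i + n_e
        frac = n_i / total if total else np.nan
        lo, hi = clopper_pearson(n_i, total, conf) if total else (np.nan, np.nan)
        rows.append({"region": region, "n_inhibitory": n_i, "n_excitatory": n_e,
                     "fraction_inhibitory": frac, "ci_low": lo, "ci_high": hi,
                     "excluded": total < min_total})
    return pd.DataFrame(rows)
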