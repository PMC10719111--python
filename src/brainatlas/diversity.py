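"""Region-level diversity and sharing statistics.

The 95%-coverage count (how many cell types, taken in descending bead-count
order, cover 95% of a region's confidently mapped beads), the weighted
Jaccard similarity between regions' cell-type weight vectors, and
dendrogram neighbourhood extraction (walk up from an index type, unioning
descendant leaves, stopping before the set would surpass 100 types or, for
a neuronal index, before absorbing a sibling set more than 60%
non-neuronal).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

__all__ = [
    "confident_type_counts",
    "types_for_coverage",
    "weighted_jaccard",
    "region_similarity",
    "CellTypeDendrogram",
    "dendrogram_neighbourhood",
]


def weighted_jaccard(a, b) -> float:
    """sum(min) / sum(max) of two non-negative weight vectors (equals the
    plain Jaccard index on 0/1 vectors)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    mx = np.maximum(a, b).sum()
    return float(np.minimum(a, b).sum() / mx) if mx > 0 else 0.0


def confident_type_counts(mapping) -> pd.DataFrame:
    """region x type table of confidently mapped bead counts."""
    conf = mapping.confidences
    sub = conf[conf["confident"]]
    return sub.pivot_table(index="region", columns="type", values="bead_id",
                           aggfunc="count", fill_value=0)


def types_for_coverage(counts: pd.Series | np.ndarray, q: float = 0.95) -> int:
    """Minimal k such that the k most frequent types cover >= q of the beads."""
    c = np.sort(np.asarray(counts, dtype=float))[::-1]
    c = c[c > 0]
    if c.size == 0 or not 0 < q <= 1:
        raise ValueError("need a region with mapped beads and 0 < q <= 1")
    cum = np.cumsum(c)
    return int(np.searchsorted(cum, q * cum[-1] - 1e-12) + 1)


def region_similarity(mapping=None, weights: pd.DataFrame | None = None) -> pd.DataFrame:
    """Weighted Jaccard similarity sum(min)/sum(max) between per-region
    cell-type weight vectors (confident-bead counts normalized per region)."""
    if weights is None:
        weights = confident_type_counts(mapping)
    W = weights.values.astype(float)
    sums = W.sum(axis=1, keepdims=True)
    norm = np.divide(W, sums, out=np.zeros_like(W), where=sums > 0)
    n = norm.shape[0]
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            mx = np.maximum(norm[i], norm[j]).sum()
            sim[i, j] = sim[j, i] = (
                np.minimum(norm[i], norm[j]).sum() / mx if mx > 0 else 0.0)
        if sums[i] > 0:
            sim[i, i] = 1.0
    return pd.DataFrame(sim, index=weights.index, columns=weights.index)


class CellTypeDendrogram:
    """Binary merge tree over terminal types, built by agglomeration on an
    aggregated between-type connectivity (or any type x type similarity)
    matrix, with per-type neuronal flags for the neighbourhood rule."""

    def __init__(self, linkage: np.ndarray, types: list[str],
                 neuronal: dict[str, bool] | None = None):
        self.linkage = linkage
        self.types = list(types)
        self.neuronal = neuronal or {t: True for t in types}
        self._tree = hierarchy.to_tree(linkage)

    @classmethod
    def from_similarity(cls, similarity: pd.DataFrame,
                        neuronal: dict[str, bool] | None = None,
                        method: str = "average") -> "CellTypeDendrogram":
        types = list(similarity.index)
        S = similarity.values.astype(float)
        smax = S.max() if S.size else 1.0
        D = smax - S
        np.fill_diagonal(D, 0.0)
        cond = D[np.triu_indices(len(types), k=1)]
        Z = hierarchy.linkage(cond, method=method)
        return cls(Z, types, neuronal)

    def _leaves(self, node) -> list[str]:
        return [self.types[i] for i in node.pre_order(lambda x: x.id)]

    def _path_to_root(self, leaf_index: int):
        """Ancestor chain from the leaf to the root."""
        path = []

        def walk(node, trail):
            if node.is_leaf():
                if node.id == leaf_index:
                    path.extend(trail + [node])
                return
            walk(node.left, trail + [node])
            walk(node.right, trail + [node])

        walk(self._tree, [])
        return list(reversed(path))  # leaf first, root last


def dendrogram_neighbourhood(dendrogram: CellTypeDendrogram, index_type: str,
                             max_types: int = 100,
                             max_non_neuronal: float = 0.6) -> set[str]:
    """Proximate neighbourhood of an index type.

    Walk to successively more distant ancestors, accumulating their
    descendant leaves; stop before the step that would push the set past
    ``max_types``, or (for a neuronal index) before absorbing a sibling set
    that is more than ``max_non_neuronal`` non-neuronal.
    """
    if index_type not in dendrogram.types:
        raise KeyError(f"unknown type {index_type!r}")
    idx = dendrogram.types.index(index_type)
    chain = dendrogram._path_to_root(idx)
    current = {index_type}
    index_is_neuronal = dendrogram.neuronal.get(index_type, True)
    for node in chain[1:]:
        candidate = set(dendrogram._leaves(node))
        added = candidate - current
        if len(candidate) > max_types:
            break
        if index_is_neuronal and added:
            non_neuronal = sum(
                not dendrogram.neuronal.get(t, True) for t in added)
            if non_neuronal / len(added) > max_non_neuronal:
                break
        current = candidate
    return current
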