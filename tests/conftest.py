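import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from brainatlas.synthetic import (CellProfileMatrix, GeneratorConfig,
                                  build_ground_truth, simulate_cells)


@pytest.fixture(scope="session")
def truth8():
    """8-type, 2-class ground truth over 300 genes (the study-scale default)."""
    return build_ground_truth(GeneratorConfig(n_types=8, n_genes=300, seed=1))


@pytest.fixture(scope="session")
def cells8(truth8):
    """2,000 cells at median depth 5,000 from the 8-type truth."""
    return simulate_cells(truth8, 2000, 5000, seed=11)


@pytest.fixture(scope="session")
def truth_small():
    return build_ground_truth(GeneratorConfig(n_types=4, n_genes=200, seed=2))


def make_cells(counts: np.ndarray, gene_ids=None, **meta_cols) -> CellProfileMatrix:
    """Dense-array helper for hand-constructed matrices."""
    counts = np.asarray(counts)
    n, g = counts.shape
    gene_ids = gene_ids or [f"g{j}" for j in range(g)]
    meta = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n)],
        "library": ["lib0"] * n,
        "donor": ["d0"] * n,
        "region": meta_cols.pop("region", ["R0"] * n),
        **meta_cols,
    })
    return CellProfileMatrix(counts=sp.csr_matrix(counts.astype(np.int64)),
                             cell_meta=meta, gene_ids=list(gene_ids))
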