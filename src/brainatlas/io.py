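"""Readers and writers for count matrices and metadata.

Counts travel as a Matrix Market triplet (matrix.mtx + barcodes.tsv +
features.tsv) or as a dense TSV; metadata as CSV. Round trips are lossless
and integer-checked.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .synthetic import BeadMatrix, CellProfileMatrix

MTX_NAME = "matrix.mtx"
BARCODES_NAME = "barcodes.tsv"
FEATURES_NAME = "features.tsv"
CELL_META_NAME = "cell_meta.csv"
BEAD_META_NAME = "bead_meta.csv"
DENSE_NAME = "counts.tsv"


def _check_counts(m: sp.spmatrix, where: str) -> sp.csr_matrix:
    m = sp.csr_matrix(m)
    if m.shape[1] == 0:
        raise ValueError(f"{where}: matrix has 0 genes")
    if m.nnz:
        bad = m.data != np.rint(m.data)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(f"{where}: non-integer count value {m.data[i]!r}")
        if (m.data < 0).any():
            raise ValueError(f"{where}: negative count values")
    return sp.csr_matrix((m.data.astype(np.int64), m.indices, m.indptr), shape=m.shape)


def write_counts(obj: CellProfileMatrix | BeadMatrix, outdir, dense: bool = False) -> Path:
    """Write counts + metadata under ``outdir`` (MTX triplet by default)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    is_beads = isinstance(obj, BeadMatrix)
    meta = obj.bead_meta if is_beads else obj.cell_meta
    ids = meta["bead_id"] if is_beads else meta["cell_id"]
    if ids.duplicated().any():
        raise ValueError("duplicate ids in metadata")
    if dense:
        df = pd.DataFrame(obj.counts.toarray(), index=ids, columns=obj.gene_ids)
        df.to_csv(outdir / DENSE_NAME, sep="\t")
    else:
        scipy.io.mmwrite(outdir / MTX_NAME, obj.counts, field="integer")
        ids.to_csv(outdir / BARCODES_NAME, sep="\t", header=False, index=False)
        pd.Series(obj.gene_ids).to_csv(outdir / FEATURES_NAME, sep="\t",
                                       header=False, index=False)
    meta.to_csv(outdir / (BEAD_META_NAME if is_beads else CELL_META_NAME), index=False)
    (outdir / "manifest.json").write_text(json.dumps({
        "kind": "beads" if is_beads else "cells",
        "layout": "dense" if dense else "mtx",
        "n_rows": int(obj.counts.shape[0]),
        "n_genes": int(obj.counts.shape[1]),
    }))
    return outdir


def read_counts(path) -> CellProfileMatrix | BeadMatrix:
    """Read a directory written by :func:`write_counts` (layout detected via
    the manifest, falling back to the files present)."""
    path = Path(path)
    manifest_file = path / "manifest.json"
    if manifest_file.exists():
        manifest = json.loads(manifest_file.read_text())
        layout = manifest["layout"]
        kind = manifest["kind"]
    else:
        layout = "mtx" if (path / MTX_NAME).exists() else "dense"
        kind = "beads" if (path / BEAD_META_NAME).exists() else "cells"

    meta_name = BEAD_META_NAME if kind == "beads" else CELL_META_NAME
    meta = pd.read_csv(path / meta_name)
    id_col = "bead_id" if kind == "beads" else "cell_id"
    if meta[id_col].duplicated().any():
        raise ValueError(f"duplicate {id_col} in {meta_name}")

    if layout == "dense":
        df = pd.read_csv(path / DENSE_NAME, sep="\t", index_col=0)
        counts = _check_counts(sp.csr_matrix(df.values), str(path))
        gene_ids = list(df.columns)
        row_ids = list(df.index.astype(str))
    else:
        counts = _check_counts(scipy.io.mmread(path / MTX_NAME), str(path))
        row_ids = pd.read_csv(path / BARCODES_NAME, sep="\t", header=None)[0].astype(str).tolist()
        gene_ids = pd.read_csv(path / FEATURES_NAME, sep="\t", header=None)[0].astype(str).tolist()

    if counts.shape[0] != len(meta) or counts.shape[0] != len(row_ids):
        raise ValueError("dimension mismatch between counts and metadata")
    if counts.shape[1] != len(gene_ids):
        raise ValueError("dimension mismatch between counts and features")
    if list(meta[id_col].astype(str)) != row_ids:
        raise ValueError("metadata ids do not match matrix row ids")

    if kind == "beads":
        return BeadMatrix(counts=counts, bead_meta=meta, gene_ids=gene_ids)
    return CellProfileMatrix(counts=counts, cell_meta=meta, gene_ids=gene_ids)
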