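"""Readers for 10x-style MTX fixtures and dense CSV matrices."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

from .containers import ExpressionDataset, GroundTruth


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required input file missing: {path}")
    return path


def read_matrix(path: str | Path, format: str = "mtx_10x",
                orientation: str = "cells_by_genes") -> ExpressionDataset:
    """Load an :class:`ExpressionDataset` from disk.

    ``mtx_10x``: a directory with matrix.mtx (genes-by-cells),
    features.tsv, barcodes.tsv and, when present, cell_meta.csv and
    embedding.csv.  ``csv``: a dense matrix with cell ids as the index and
    gene ids as columns (or transposed; declare via ``orientation``).
    The in-memory orientation is always cells-by-genes.
    """
    path = Path(path)
    if format == "mtx_10x":
        return _read_mtx_dir(path)
    if format == "csv":
        df = pd.read_csv(_require(path), index_col=0)
        if orientation == "genes_by_cells":
            df = df.T
        elif orientation != "cells_by_genes":
            raise ValueError(f"unknown orientation {orientation!r}")
        counts = df.to_numpy()
        if not np.allclose(counts, np.round(counts)):
            raise ValueError(f"{path}: counts must be integral")
        gene_meta = pd.DataFrame(
            {"gene_id": df.columns, "is_mito": [g.lower().startswith("mt-") for g in df.columns]}
        )
        cell_meta = pd.DataFrame(
            {
                "cell_id": df.index.astype(str),
                "sample_id": "sample", "timepoint": "sample",
                "population": "unknown", "lineage": "unknown",
                "pseudotime": np.nan,
            }
        )
        return ExpressionDataset(
            counts=counts.astype(np.int64),
            cell_meta=cell_meta,
            gene_meta=gene_meta,
            embedding=np.zeros((len(df), 2)),
        )
    raise ValueError(f"unknown format {format!r} (use 'mtx_10x' or 'csv')")


def _read_mtx_dir(d: Path) -> ExpressionDataset:
    mat = mmread(_require(d / "matrix.mtx"))
    counts = np.asarray(mat.todense()).T.astype(np.int64)  # -> cells x genes
    feats = pd.read_csv(_require(d / "features.tsv"), sep="\t", header=None)
    barcodes = pd.read_csv(_require(d / "barcodes.tsv"), sep="\t", header=None)[0].astype(str)
    if len(feats) != counts.shape[1]:
        raise ValueError(
            f"{d / 'features.tsv'}: {len(feats)} features but matrix has "
            f"{counts.shape[1]} gene rows"
        )
    if len(barcodes) != counts.shape[0]:
        raise ValueError(
            f"{d / 'barcodes.tsv'}: {len(barcodes)} barcodes but matrix has "
            f"{counts.shape[0]} cell columns"
        )
    gene_ids = feats[0].astype(str)
    gene_meta = pd.DataFrame(
        {"gene_id": gene_ids, "is_mito": [g.lower().startswith("mt-") for g in gene_ids]}
    )

    meta_path = d / "cell_meta.csv"
    if meta_path.exists():
        cell_meta = pd.read_csv(meta_path)
        if len(cell_meta) != counts.shape[0]:
            raise ValueError(f"{meta_path}: rows do not match the matrix cell count")
        cell_meta = cell_meta.set_index("cell_id").loc[barcodes].reset_index()
    else:
        cell_meta = pd.DataFrame(
            {
                "cell_id": barcodes, "sample_id": "sample", "timepoint": "sample",
                "population": "unknown", "lineage": "unknown", "pseudotime": np.nan,
            }
        )

    emb_path = d / "embedding.csv"
    if emb_path.exists():
        emb_df = pd.read_csv(emb_path).set_index("cell_id").loc[barcodes]
        embedding = emb_df[["x", "y"]].to_numpy(dtype=float)
    else:
        embedding = np.zeros((counts.shape[0], 2))

    return ExpressionDataset(
        counts=counts, cell_meta=cell_meta, gene_meta=gene_meta, embedding=embedding
    )


def read_ground_truth(path: str | Path) -> GroundTruth:
    import json

    with open(_require(Path(path))) as fh:
        return GroundTruth.from_dict(json.load(fh))
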