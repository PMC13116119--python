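"""Shared in-memory containers for the pipeline.

``ExpressionDataset`` carries the cells-by-genes count matrix, its
log-normalized layer, per-cell metadata, the 2-D embedding and per-gene
metadata, aligned row-for-row / column-for-column.  ``GroundTruth`` carries
everything the synthetic simulator knows that a real experiment would not:
the true weighted GRN, lineage assignments, pseudotime and the abundance
design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

CELL_META_COLUMNS = ["cell_id", "sample_id", "timepoint", "population", "lineage", "pseudotime"]


@dataclass
class ExpressionDataset:
    """Aligned single-cell expression container.

    Parameters
    ----------
    counts
        Cells-by-genes non-negative integer matrix (dense ndarray).
    cell_meta
        One row per cell with at least the columns in
        :data:`CELL_META_COLUMNS` (``pseudotime`` may be NaN).
    gene_meta
        One row per gene with columns ``gene_id`` and ``is_mito``.
    embedding
        Cells-by-2 real coordinates.
    norm
        Optional log-normalized layer with the same shape as ``counts``.
    """

    counts: np.ndarray
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame
    embedding: np.ndarray
    norm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.embedding = np.asarray(self.embedding, dtype=float)
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.gene_meta["gene_id"].to_numpy())

    @property
    def cell_ids(self) -> pd.Index:
        return pd.Index(self.cell_meta["cell_id"].to_numpy())

    def gene_index(self, names: Sequence[str]) -> np.ndarray:
        """Column indices of ``names`` (raises on unknown genes)."""
        idx = self.genes.get_indexer(list(names))
        if (idx < 0).any():
            missing = [n for n, i in zip(names, idx) if i < 0]
            raise KeyError(f"genes not in dataset: {missing[:5]}")
        return idx

    def validate(self) -> None:
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (cells x genes)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        n, g = self.counts.shape
        if len(self.cell_meta) != n:
            raise ValueError("cell_meta rows must align with counts rows")
        if len(self.gene_meta) != g:
            raise ValueError("gene_meta rows must align with counts columns")
        if self.embedding.shape != (n, 2):
            raise ValueError("embedding must be cells x 2")
        if self.norm is not None:
            self.norm = np.asarray(self.norm, dtype=float)
            if self.norm.shape != (n, g):
                raise ValueError("norm layer must match counts shape")
            if np.any(self.norm < 0):
                raise ValueError("norm layer must be non-negative")

    # -- manipulation ---------------------------------------------------
    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            counts=self.counts.copy(),
            cell_meta=self.cell_meta.copy().reset_index(drop=True),
            gene_meta=self.gene_meta.copy().reset_index(drop=True),
            embedding=self.embedding.copy(),
            norm=None if self.norm is None else self.norm.copy(),
        )

    def subset_cells(self, mask: np.ndarray) -> "ExpressionDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return ExpressionDataset(
            counts=self.counts[idx],
            cell_meta=self.cell_meta.iloc[idx].reset_index(drop=True),
            gene_meta=self.gene_meta.copy().reset_index(drop=True),
            embedding=self.embedding[idx],
            norm=None if self.norm is None else self.norm[idx],
        )

    def to_anndata(self):
        """Export to :class:`anndata.AnnData` (counts in X, norm as layer)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.astype(np.float32),
            obs=self.cell_meta.set_index("cell_id"),
            var=self.gene_meta.set_index("gene_id"),
        )
        adata.obsm["X_embed"] = self.embedding.copy()
        if self.norm is not None:
            adata.layers["lognorm"] = self.norm.copy()
        return adata


@dataclass
class GroundTruth:
    """What the simulator planted: the quantities inference should recover.

    ``grn_weights`` is a TF-by-gene signed weight table (rows = TFs,
    columns = all genes; zero where no edge).  ``driver_map`` names, per
    lineage, the dedicated driver TF(s) whose activity ramps up along that
    lineage's pseudotime.  ``abundance_multiplier`` is the population-by-
    timepoint relative abundance design (baseline column = 1).
    ``lineage_of_cell`` / ``pseudotime_true`` are filled by
    :func:`scregflow.synthetic.simulate_cells`.
    """

    grn_weights: pd.DataFrame
    driver_map: dict[str, list[str]]
    abundance_multiplier: pd.DataFrame
    seed: int
    lineage_of_cell: np.ndarray | None = None
    pseudotime_true: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.abundance_multiplier.to_numpy() <= 0).any():
            raise ValueError("abundance_multiplier must be positive everywhere")
        for lin, drivers in self.driver_map.items():
            for tf in drivers:
                if not (self.grn_weights.loc[tf] != 0).any():
                    raise ValueError(f"driver TF {tf} of lineage {lin} has no outgoing edge")

    @property
    def tfs(self) -> list[str]:
        return list(self.grn_weights.index)

    @property
    def lineages(self) -> list[str]:
        return list(self.driver_map)

    def edges(self) -> pd.DataFrame:
        """Long-format nonzero edges (tf, target, weight)."""
        w = self.grn_weights
        tf_idx, g_idx = np.nonzero(w.to_numpy())
        return pd.DataFrame(
            {
                "tf": w.index.to_numpy()[tf_idx],
                "target": w.columns.to_numpy()[g_idx],
                "weight": w.to_numpy()[tf_idx, g_idx],
            }
        )

    def to_dict(self) -> dict:
        d = {
            "grn_weights": {
                "index": list(self.grn_weights.index),
                "columns": list(self.grn_weights.columns),
                "values": self.grn_weights.to_numpy().tolist(),
            },
            "driver_map": {k: list(v) for k, v in self.driver_map.items()},
            "abundance_multiplier": {
                "index": list(self.abundance_multiplier.index),
                "columns": list(self.abundance_multiplier.columns),
                "values": self.abundance_multiplier.to_numpy().tolist(),
            },
            "seed": int(self.seed),
            "lineage_of_cell": None
            if self.lineage_of_cell is None
            else [str(x) for x in self.lineage_of_cell],
            "pseudotime_true": None
            if self.pseudotime_true is None
            else [float(x) for x in self.pseudotime_true],
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        gw = pd.DataFrame(
            np.asarray(d["grn_weights"]["values"], dtype=float),
            index=d["grn_weights"]["index"],
            columns=d["grn_weights"]["columns"],
        )
        am = pd.DataFrame(
            np.asarray(d["abundance_multiplier"]["values"], dtype=float),
            index=d["abundance_multiplier"]["index"],
            columns=d["abundance_multiplier"]["columns"],
        )
        return cls(
            grn_weights=gw,
            driver_map={k: list(v) for k, v in d["driver_map"].items()},
            abundance_multiplier=am,
            seed=int(d["seed"]),
            lineage_of_cell=None
            if d.get("lineage_of_cell") is None
            else np.asarray(d["lineage_of_cell"], dtype=object),
            pseudotime_true=None
            if d.get("pseudotime_true") is None
            else np.asarray(d["pseudotime_true"], dtype=float),
        )

    def __eq__(self, other: object) -> bool:  # value equality for round-trips
        if not isinstance(other, GroundTruth):
            return NotImplemented
        same = (
            self.grn_weights.equals(other.grn_weights)
            and self.driver_map == other.driver_map
            and self.abundance_multiplier.equals(other.abundance_multiplier)
            and self.seed == other.seed
        )
        if not same:
            return False
        for a, b in (
            (self.lineage_of_cell, other.lineage_of_cell),
            (self.pseudotime_true, other.pseudotime_true),
        ):
            if (a is None) != (b is None):
                return False
            if a is not None and not np.array_equal(a, b):
                return False
        return True
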