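"""Cell quality control and normalization.

QC follows the standard droplet heuristics: drop cells with fewer than 500
or more than 5000 expressed genes, and cells with more than 20% of UMIs
from mitochondrial genes.  The expression layer used downstream is
library-size log-normalization, log(1 + scale * count / total); batches are
assumed pre-integrated.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .containers import ExpressionDataset


@dataclass
class QCReport:
    """Tally of the cell-filtering outcome.

    Each failure mode is counted independently, so a cell violating two
    rules increments two counters; ``n_retained`` plus the number of cells
    failing at least one rule equals ``n_input_cells``.
    """

    n_input_cells: int
    n_retained: int
    n_failed_low_genes: int
    n_failed_high_genes: int
    n_failed_mito: int
    thresholds: tuple[int, int, float]

    def to_json(self) -> str:
        d = asdict(self)
        d["thresholds"] = list(d["thresholds"])
        return json.dumps(d, indent=2)


def expressed_gene_counts(ds: ExpressionDataset) -> np.ndarray:
    """Number of genes with count > 0 per cell."""
    return np.count_nonzero(ds.counts > 0, axis=1)


def mito_fractions(ds: ExpressionDataset) -> np.ndarray:
    """Fraction of UMIs from mitochondrial genes per cell (0 for empty cells)."""
    is_mito = ds.gene_meta["is_mito"].to_numpy(dtype=bool)
    total = ds.counts.sum(axis=1).astype(float)
    mito = ds.counts[:, is_mito].sum(axis=1).astype(float) if is_mito.any() else np.zeros(ds.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1e-300), 0.0)
    return frac


def filter_cells(
    ds: ExpressionDataset,
    min_genes: int = 500,
    max_genes: int = 5000,
    max_mito_frac: float = 0.20,
) -> tuple[ExpressionDataset, QCReport]:
    """Apply the three cell-quality filters simultaneously.

    A cell is retained when its expressed-gene count lies in
    ``[min_genes, max_genes]`` (both boundaries inclusive: "fewer than
    min" and "more than max" are removed) and its mitochondrial UMI
    fraction is at most ``max_mito_frac`` (strictly "over" is removed).
    """
    n_expr = expressed_gene_counts(ds)
    mito = mito_fractions(ds)

    fail_low = n_expr < min_genes
    fail_high = n_expr > max_genes
    fail_mito = mito > max_mito_frac
    keep = ~(fail_low | fail_high | fail_mito)

    report = QCReport(
        n_input_cells=ds.n_cells,
        n_retained=int(keep.sum()),
        n_failed_low_genes=int(fail_low.sum()),
        n_failed_high_genes=int(fail_high.sum()),
        n_failed_mito=int(fail_mito.sum()),
        thresholds=(min_genes, max_genes, max_mito_frac),
    )
    if report.n_retained == 0:
        raise ValueError(
            "QC removed every cell "
            f"(thresholds min_genes={min_genes}, max_genes={max_genes}, "
            f"max_mito_frac={max_mito_frac}); check that the thresholds suit the gene panel"
        )
    return ds.subset_cells(keep), report


def lognormalize(ds: ExpressionDataset, scale: float = 1e4) -> ExpressionDataset:
    """Fill the ``norm`` layer with log1p library-size-normalized counts.

    norm[i, g] = log(1 + scale * counts[i, g] / total_counts[i]).
    Returns a copy; the input is untouched.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    total = ds.counts.sum(axis=1).astype(float)
    zero = np.flatnonzero(total == 0)
    if zero.size:
        ids = ds.cell_meta["cell_id"].iloc[zero[:5]].tolist()
        raise ValueError(f"cells with zero total counts cannot be normalized: {ids}")
    out = ds.copy()
    out.norm = np.log1p(scale * ds.counts / total[:, None])
    return out


def zscore_genes(matrix: np.ndarray) -> np.ndarray:
    """Z-score each column (feature) to mean 0, sd 1 (population sd).

    Zero-variance columns map to all-zeros rather than NaN so that rank-
    based downstream scores never see NaNs.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("zscore_genes needs a 2-D matrix with at least 2 rows")
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    out = np.zeros_like(x)
    ok = sd > 0
    out[:, ok] = (x[:, ok] - mean[ok]) / sd[ok]
    return out
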