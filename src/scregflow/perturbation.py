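"""In-silico TF knock-in / knock-out with a flow-field readout.

A linear GRN (per-population ridge fits restricted to the allowed edge
set) propagates the expression shift imposed by clamping one TF: knock-out
pins the TF at 0, knock-in at max(1, 2 x 95th percentile of its observed
expression).  The propagated per-cell shift is projected onto the 2-D
embedding by comparing each cell's shift with its neighbors' expression
offsets (softmax transition probabilities, drift-corrected), yielding a
perturbed flow.  The developmental flow is the gradient of kernel-smoothed
pseudotime on an embedding grid, and the perturbation score (PS) at each
occupied grid point is the inner product of the two flows; lineage-level
PS is the mean over grid points whose majority occupant belongs to that
lineage.  Positive PS: the perturbation pushes cells along the lineage's
differentiation direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import CellGraph
from .containers import ExpressionDataset, GroundTruth
from .regulons import RegulonSet


@dataclass
class LinearGRN:
    """Per-stratum gene-by-regulator coefficient matrices on allowed edges."""

    coef: dict[str, np.ndarray]  # stratum -> genes x genes, C[target, regulator]
    genes: list[str]
    strata: list[str]
    ridge_alpha: float
    base_edges: np.ndarray  # genes x genes boolean allowed mask

    def matrix_for(self, stratum: str) -> np.ndarray:
        return self.coef.get(stratum, self.coef["global"])


@dataclass
class PerturbationSpec:
    tf: str
    mode: str  # {KI, KO}
    target_value: float
    n_propagation: int = 3

    def __post_init__(self) -> None:
        if self.mode not in ("KI", "KO"):
            raise ValueError("mode must be 'KI' or 'KO'")
        if self.mode == "KO" and self.target_value != 0:
            raise ValueError("knock-out target value must be 0")
        if self.mode == "KI" and self.target_value < 1:
            raise ValueError("knock-in target value must be at least 1")
        if self.n_propagation < 1:
            raise ValueError("n_propagation must be at least 1")

    @classmethod
    def knockout(cls, tf: str, n_propagation: int = 3) -> "PerturbationSpec":
        return cls(tf=tf, mode="KO", target_value=0.0, n_propagation=n_propagation)

    @classmethod
    def knockin(cls, tf: str, ds: ExpressionDataset, n_propagation: int = 3) -> "PerturbationSpec":
        if ds.norm is None:
            raise ValueError("dataset needs a normalized layer")
        value = knockin_value(ds.norm[:, ds.gene_index([tf])[0]])
        return cls(tf=tf, mode="KI", target_value=value, n_propagation=n_propagation)


@dataclass
class DevelopmentalFlow:
    """Pseudotime-gradient flow on an embedding grid."""

    grid_points: np.ndarray  # n_grid x 2 centers (row-major over y within x)
    vectors: np.ndarray  # n_grid x 2, toward increasing pseudotime
    occupancy: np.ndarray  # cells per grid point
    mask: np.ndarray  # occupied grid points carrying vectors
    grid_bins: int
    bin_of_cell: np.ndarray  # flat grid index per cell


@dataclass
class FlowField:
    cell_vectors: np.ndarray  # cells x 2 perturbation displacement
    grid_vectors: np.ndarray  # n_grid x 2 aggregated
    dev_vectors: np.ndarray  # n_grid x 2 developmental flow
    grid_spec: tuple[int, int]  # (bins per axis, occupancy threshold)
    ps_per_grid: np.ndarray  # inner products at occupied grid points (NaN elsewhere)
    ps_per_lineage: dict[str, float]


def fit_linear_grn(
    ds: ExpressionDataset,
    base: RegulonSet | GroundTruth | pd.DataFrame,
    ridge_alpha: float = 1.0,
    stratify: str = "population",
    min_stratum_cells: int = 20,
) -> LinearGRN:
    """Ridge-fit every target gene on its allowed regulators.

    ``base`` supplies the allowed edge set (an inferred regulon set, the
    simulator's ground truth, or a boolean TF-by-gene frame).  Fits are
    per population with a global fallback for strata below
    ``min_stratum_cells``; a 'global' fit over all cells is always
    included.  Genes without allowed regulators stay inert (zero rows).
    """
    if ds.norm is None:
        raise ValueError("dataset needs a normalized layer (run lognormalize first)")
    genes = list(ds.genes)
    gpos = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    allowed = np.zeros((n_genes, n_genes), dtype=bool)  # [target, regulator]
    if isinstance(base, RegulonSet):
        edge_iter = ((tf, g) for tf, tg in base.regulons.items() for g, _ in tg)
    elif isinstance(base, GroundTruth):
        edge_iter = ((r.tf, r.target) for r in base.edges().itertuples())
    elif isinstance(base, pd.DataFrame):
        edge_iter = (
            (tf, g)
            for tf in base.index
            for g in base.columns
            if bool(base.loc[tf, g])
        )
    else:
        raise TypeError("base must be a RegulonSet, GroundTruth, or boolean DataFrame")
    for tf, g in edge_iter:
        if tf in gpos and g in gpos and tf != g:
            allowed[gpos[g], gpos[tf]] = True

    if stratify == "population":
        labels = ds.cell_meta["population"].to_numpy()
        strata = [str(s) for s in pd.unique(labels)]
    elif stratify == "global":
        labels = np.full(ds.n_cells, "global", dtype=object)
        strata = []
    else:
        raise ValueError("stratify must be 'population' or 'global'")

    def _fit(cell_idx: np.ndarray) -> np.ndarray:
        X = ds.norm[cell_idx]
        C = np.zeros((n_genes, n_genes))
        xc = X - X.mean(axis=0)
        for t in range(n_genes):
            regs = np.flatnonzero(allowed[t])
            if regs.size == 0:
                continue
            Xr = xc[:, regs]
            y = xc[:, t]
            beta = np.linalg.solve(
                Xr.T @ Xr + ridge_alpha * np.eye(regs.size), Xr.T @ y
            )
            C[t, regs] = beta
        return C

    coef = {"global": _fit(np.arange(ds.n_cells))}
    kept = ["global"]
    for s in strata:
        idx = np.flatnonzero(labels == s)
        if idx.size < min_stratum_cells:
            warnings.warn(
                f"stratum {s!r} has {idx.size} cells (<{min_stratum_cells}); "
                "falling back to the global fit",
                stacklevel=2,
            )
            continue
        coef[s] = _fit(idx)
        kept.append(s)
    return LinearGRN(
        coef=coef, genes=genes, strata=kept, ridge_alpha=ridge_alpha, base_edges=allowed
    )


def knockin_value(tf_expression: np.ndarray) -> float:
    """max(1, 2 x 95th percentile) of observed expression (linear-
    interpolation percentile convention)."""
    v = np.asarray(tf_expression, dtype=float)
    if v.size == 0:
        raise ValueError("expression vector is empty")
    if (v < 0).any():
        raise ValueError("expression must be non-negative")
    return float(max(1.0, 2.0 * np.percentile(v, 95)))


def simulate_shift(
    grn: LinearGRN,
    ds: ExpressionDataset,
    spec: PerturbationSpec,
    clamp: bool = True,
) -> np.ndarray:
    """Propagate the perturbation through the linear GRN.

    Per cell, the initial shift is target_value - x[tf] on the TF
    coordinate.  Each of ``spec.n_propagation`` iterations applies the
    stratum coefficient matrix, re-pins the TF coordinate, and (when
    ``clamp``) prevents simulated expression x + delta from going below 0.
    Returns the cells-by-genes shift after the final iteration.
    """
    if ds.norm is None:
        raise ValueError("dataset needs a normalized layer")
    if spec.tf not in grn.genes:
        raise KeyError(f"TF {spec.tf!r} not in the fitted GRN")
    tf_idx = grn.genes.index(spec.tf)
    if not any(grn.coef[s][:, tf_idx].any() for s in grn.coef):
        warnings.warn(
            f"TF {spec.tf!r} has no outgoing coefficients; "
            "the shift is confined to the TF itself",
            stacklevel=2,
        )

    x = ds.norm
    n = ds.n_cells
    delta = np.zeros_like(x)
    delta0_tf = spec.target_value - x[:, tf_idx]
    delta[:, tf_idx] = delta0_tf

    labels = ds.cell_meta["population"].astype(str).to_numpy()
    for stratum in pd.unique(labels):
        m = labels == stratum
        C = grn.matrix_for(str(stratum))
        d = delta[m]
        for _ in range(spec.n_propagation):
            d = d @ C.T
            d[:, tf_idx] = delta0_tf[m]
            if clamp:
                np.maximum(d, -x[m], out=d)
        delta[m] = d
    return delta


def project_flow(
    shift: np.ndarray,
    ds: ExpressionDataset,
    graph: CellGraph,
    kernel_scale: float = 0.05,
) -> np.ndarray:
    """Project expression shifts onto the embedding as per-cell 2-D vectors.

    For cell i, the Pearson correlation between its shift vector and each
    neighbor's expression offset x_j - x_i is turned into transition
    probabilities by a softmax at temperature ``kernel_scale``; the flow
    vector is the probability-weighted mean of unit embedding directions
    minus the uniform-neighbor baseline (drift correction).  Cells with a
    zero shift get a zero vector.
    """
    if ds.norm is None:
        raise ValueError("dataset needs a normalized layer")
    if graph.n_cells != ds.n_cells:
        raise ValueError("graph was built on a different number of cells")
    x = ds.norm
    emb = ds.embedding
    n = ds.n_cells
    vectors = np.zeros((n, 2))
    for i in range(n):
        d = shift[i]
        if not np.any(d):
            continue
        nbrs = graph.knn_indices[i]
        diff = x[nbrs] - x[i]  # k x genes
        dc = d - d.mean()
        dnorm = np.linalg.norm(dc)
        diffc = diff - diff.mean(axis=1, keepdims=True)
        dennorm = np.linalg.norm(diffc, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (diffc @ dc) / (dennorm * dnorm)
        corr = np.where(np.isfinite(corr), corr, 0.0)

        logits = corr / kernel_scale
        logits -= logits.max()
        p = np.exp(logits)
        p /= p.sum()

        e = emb[nbrs] - emb[i]
        norms = np.linalg.norm(e, axis=1)
        unit = np.divide(e, norms[:, None], out=np.zeros_like(e), where=norms[:, None] > 0)
        vectors[i] = p @ unit - unit.mean(axis=0)
    return vectors


def _grid_geometry(emb: np.ndarray, grid_bins: int):
    lo = emb.min(axis=0)
    hi = emb.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    edges_x = np.linspace(lo[0], lo[0] + span[0], grid_bins + 1)
    edges_y = np.linspace(lo[1], lo[1] + span[1], grid_bins + 1)
    cx = 0.5 * (edges_x[:-1] + edges_x[1:])
    cy = 0.5 * (edges_y[:-1] + edges_y[1:])
    gx, gy = np.meshgrid(cx, cy, indexing="ij")
    points = np.stack([gx.ravel(), gy.ravel()], axis=1)
    ix = np.clip(np.searchsorted(edges_x, emb[:, 0], side="right") - 1, 0, grid_bins - 1)
    iy = np.clip(np.searchsorted(edges_y, emb[:, 1], side="right") - 1, 0, grid_bins - 1)
    flat = ix * grid_bins + iy
    return points, flat, (cx, cy)


def development_flow(
    ds: ExpressionDataset,
    grid_bins: int = 40,
    smooth_sigma: float | None = None,
    min_cells: int = 3,
) -> DevelopmentalFlow:
    """Gradient of kernel-smoothed pseudotime on an embedding grid.

    Pseudotime is smoothed onto a ``grid_bins`` x ``grid_bins`` lattice
    with a Gaussian kernel (default bandwidth: 1.5 grid cells) and the
    developmental vector is its finite-difference gradient, pointing
    toward increasing pseudotime; grid points with fewer than
    ``min_cells`` occupants carry no vector.
    """
    pt = ds.cell_meta["pseudotime"].to_numpy(dtype=float)
    if np.isnan(pt).any():
        raise ValueError("pseudotime must be present for every cell")
    emb = ds.embedding
    points, flat, (cx, cy) = _grid_geometry(emb, grid_bins)
    occupancy = np.bincount(flat, minlength=grid_bins * grid_bins)
    if (occupancy > 0).sum() < 2:
        raise ValueError("all cells fall in one grid bin; use a finer grid")

    if smooth_sigma is None:
        smooth_sigma = 1.5 * max(cx[1] - cx[0] if len(cx) > 1 else 1.0,
                                 cy[1] - cy[0] if len(cy) > 1 else 1.0)
    d2 = ((points[:, None, :] - emb[None, :, :]) ** 2).sum(axis=2)
    w = np.exp(-d2 / (2 * smooth_sigma**2))
    wsum = w.sum(axis=1)
    smoothed = (w @ pt) / np.maximum(wsum, 1e-300)
    field = smoothed.reshape(grid_bins, grid_bins)

    dx = cx[1] - cx[0] if len(cx) > 1 else 1.0
    dy = cy[1] - cy[0] if len(cy) > 1 else 1.0
    gx, gy = np.gradient(field, dx, dy)
    vectors = np.stack([gx.ravel(), gy.ravel()], axis=1)
    mask = occupancy >= min_cells
    vectors[~mask] = 0.0
    return DevelopmentalFlow(
        grid_points=points, vectors=vectors, occupancy=occupancy,
        mask=mask, grid_bins=grid_bins, bin_of_cell=flat,
    )


def perturbation_score(
    cell_vectors: np.ndarray,
    dev: DevelopmentalFlow,
    lineage_of_cell: np.ndarray,
) -> FlowField:
    """Grid-aggregated inner product of perturbed and developmental flow.

    Cell vectors are averaged per occupied grid point; the PS at a point
    is the raw inner product with the developmental vector, and the
    lineage PS is the mean over grid points whose majority occupant
    lineage matches.
    """
    lineage_of_cell = np.asarray(lineage_of_cell)
    n_grid = dev.grid_points.shape[0]
    grid_vectors = np.zeros((n_grid, 2))
    np.add.at(grid_vectors, dev.bin_of_cell, cell_vectors)
    occ = np.maximum(dev.occupancy, 1)
    grid_vectors /= occ[:, None]
    grid_vectors[~dev.mask] = 0.0

    ps = np.full(n_grid, np.nan)
    ps[dev.mask] = np.einsum("ij,ij->i", grid_vectors[dev.mask], dev.vectors[dev.mask])

    majority = {}
    for b in np.flatnonzero(dev.mask):
        occupants = lineage_of_cell[dev.bin_of_cell == b]
        if occupants.size:
            vals, counts = np.unique(occupants.astype(str), return_counts=True)
            majority[b] = vals[np.argmax(counts)]
    ps_per_lineage: dict[str, float] = {}
    for lin in pd.unique(lineage_of_cell.astype(str)):
        bins = [b for b, m in majority.items() if m == lin]
        if not bins:
            warnings.warn(f"lineage {lin!r} occupies no grid point; PS missing", stacklevel=2)
            ps_per_lineage[lin] = float("nan")
        else:
            ps_per_lineage[lin] = float(np.mean(ps[bins]))
    return FlowField(
        cell_vectors=cell_vectors,
        grid_vectors=grid_vectors,
        dev_vectors=dev.vectors,
        grid_spec=(dev.grid_bins, 0 if dev.mask.all() else int(dev.occupancy[dev.mask].min())),
        ps_per_grid=ps,
        ps_per_lineage=ps_per_lineage,
    )


def perturb_and_score(
    ds: ExpressionDataset,
    grn: LinearGRN,
    spec: PerturbationSpec,
    graph: CellGraph,
    dev: DevelopmentalFlow | None = None,
    grid_bins: int = 40,
    kernel_scale: float = 0.05,
) -> FlowField:
    """Convenience end-to-end: shift -> flow -> PS for one perturbation."""
    if dev is None:
        dev = development_flow(ds, grid_bins=grid_bins)
    shift = simulate_shift(grn, ds, spec)
    vectors = project_flow(shift, ds, graph, kernel_scale=kernel_scale)
    return perturbation_score(vectors, dev, ds.cell_meta["lineage"].to_numpy())
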