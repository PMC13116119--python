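"""Seeded synthetic single-cell datasets with a known regulatory network.

The generator emulates a bone-marrow progenitor time course: ~8 HSPC-like
subpopulations sampled at a baseline plus five post-exposure timepoints,
with timepoint-dependent abundance shifts, three branching lineages
(megakaryocyte-erythroid ME, granulocyte-macrophage GM, lymphoid LY) with
pseudotime, and target genes causally driven by transcription factors
through a known weighted GRN under negative-binomial count noise.

Design, fixed once:

* Each lineage has one dedicated driver TF whose mean expression ramps
  linearly with pseudotime within its own lineage; driver TFs carry
  positive weights onto a disjoint lineage-specific target block.
* All TFs additionally fluctuate cell-to-cell through a log-normal latent
  factor, so non-driver edges are statistically identifiable.
* Target mean = clamped-linear link of the TF means through the true
  weights (keeps the planted GRN linear, so a linear fit is well
  specified).
* Counts ~ NB(mean mu, shape r): var = mu + mu^2 / r; r = inf gives the
  Poisson limit.
* The embedding is a deterministic branch layout (root at the origin,
  branches at fixed angles, radius proportional to pseudotime) plus small
  Gaussian jitter — not a recomputed UMAP — so flow-field tests are
  reproducible.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmwrite

from .containers import ExpressionDataset, GroundTruth
from .preprocessing import lognormalize

DEFAULT_TIMEPOINTS = ["D0", "D1", "D3", "D7", "D14", "D21"]
DEFAULT_LINEAGES = ["ME", "GM", "LY"]

# population -> (lineage or None for root, pseudotime range, baseline fraction)
DEFAULT_POPULATIONS: dict[str, tuple[str | None, float, float, float]] = {
    "LT-HSC": (None, 0.00, 0.18, 0.10),
    "ST-HSC": (None, 0.12, 0.32, 0.15),
    "MPP2": ("ME", 0.30, 0.68, 0.12),
    "MEP": ("ME", 0.62, 1.00, 0.12),
    "MPP3": ("GM", 0.30, 0.68, 0.15),
    "GMP": ("GM", 0.62, 1.00, 0.14),
    "MPP4": ("LY", 0.30, 0.68, 0.12),
    "CLP": ("LY", 0.62, 1.00, 0.10),
}

# Relative abundance design (population x timepoint, baseline D0 = 1):
# sustained HSC/MPP depletion, a shared committed-progenitor expansion on
# D1, an MEP/CLP dip-and-recovery, and a progressive GMP increase.
DEFAULT_ABUNDANCE = pd.DataFrame(
    [
        [1.0, 1.10, 0.70, 0.50, 0.40, 0.35],
        [1.0, 0.80, 0.60, 0.50, 0.45, 0.40],
        [1.0, 0.90, 0.70, 0.60, 0.50, 0.45],
        [1.0, 1.60, 0.60, 0.90, 1.20, 1.10],
        [1.0, 0.90, 0.80, 0.70, 0.60, 0.50],
        [1.0, 1.50, 1.80, 2.20, 2.60, 3.00],
        [1.0, 0.85, 0.70, 0.60, 0.55, 0.50],
        [1.0, 1.40, 0.50, 0.80, 1.10, 1.00],
    ],
    index=list(DEFAULT_POPULATIONS),
    columns=DEFAULT_TIMEPOINTS,
)

# branch angles (degrees) for the deterministic embedding layout
_BRANCH_ANGLES = {"ME": 90.0, "GM": 210.0, "LY": 330.0}

_N_MITO_GENES = 5

# activation-curve / link-function constants (see docs/methods.md)
_TF_BASE_MEAN = 0.4
_TF_LATENT_SD = 0.5
_DRIVER_AMPLITUDE = 5.0
_TARGET_BASELINE = 0.2
_TARGET_FLOOR = 0.02
_MITO_MEAN = 0.8
_EMBED_RADIUS = 8.0
_EMBED_JITTER = 0.35


def _generic_populations(lineages: list[str]) -> tuple[dict, pd.DataFrame]:
    pops: dict[str, tuple[str | None, float, float, float]] = {
        "Root": (None, 0.0, 0.3, 0.25)
    }
    frac = 0.75 / len(lineages)
    for lin in lineages:
        pops[f"{lin}-prog"] = (lin, 0.3, 1.0, frac)
    ab = pd.DataFrame(1.0, index=list(pops), columns=DEFAULT_TIMEPOINTS)
    return pops, ab


def simulate_grn(
    n_tfs: int,
    n_targets: int,
    lineages: list[str] | None = None,
    density: float = 0.05,
    seed: int = 0,
    populations: dict | None = None,
    timepoints: list[str] | None = None,
    abundance_multiplier: pd.DataFrame | None = None,
    p_driver_edge: float = 0.8,
) -> GroundTruth:
    """Draw a ground-truth GRN with one dedicated driver TF per lineage.

    The first ``len(lineages)`` TFs are the drivers; each receives positive
    weights onto its own disjoint block of ``n_targets // n_lineages``
    target genes (each block gene with probability ``p_driver_edge``, the
    first one always).  The remaining TF-target pairs get signed edges at
    the given ``density``.
    """
    lineages = list(lineages) if lineages is not None else list(DEFAULT_LINEAGES)
    if n_tfs < len(lineages):
        raise ValueError(f"need at least one TF per lineage: n_tfs={n_tfs} < {len(lineages)}")
    if not (0 <= density <= 1):
        raise ValueError("density must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    tf_names = [f"Tf{i + 1:02d}" for i in range(n_tfs)]
    target_names = [f"Gene{i + 1:03d}" for i in range(n_targets)]
    mito_names = [f"mt-Gene{i + 1}" for i in range(_N_MITO_GENES)]
    genes = tf_names + target_names + mito_names

    w = pd.DataFrame(0.0, index=tf_names, columns=genes)
    driver_map: dict[str, list[str]] = {}
    block = n_targets // len(lineages)
    for li, lin in enumerate(lineages):
        tf = tf_names[li]
        driver_map[lin] = [tf]
        block_genes = target_names[li * block : (li + 1) * block]
        take = rng.random(len(block_genes)) < p_driver_edge
        take[0] = True  # at least one positive driver edge
        for g, t in zip(block_genes, take):
            if t:
                w.loc[tf, g] = rng.uniform(1.0, 2.0)

    if density > 0:
        for tf in tf_names:
            for g in target_names:
                if w.loc[tf, g] == 0 and rng.random() < density:
                    w.loc[tf, g] = rng.choice([-1.0, 1.0]) * rng.uniform(0.2, 0.6)

    if populations is None:
        if lineages == DEFAULT_LINEAGES:
            populations = dict(DEFAULT_POPULATIONS)
            ab = DEFAULT_ABUNDANCE.copy()
        else:
            populations, ab = _generic_populations(lineages)
    else:
        ab = None
    if abundance_multiplier is not None:
        ab = abundance_multiplier.copy()
    if ab is None:
        ab = pd.DataFrame(
            1.0,
            index=list(populations),
            columns=list(timepoints) if timepoints else DEFAULT_TIMEPOINTS,
        )
    if timepoints is not None:
        ab = ab.loc[:, list(timepoints)]

    truth = GroundTruth(
        grn_weights=w, driver_map=driver_map, abundance_multiplier=ab, seed=int(seed)
    )
    truth.populations = populations  # layout consumed by simulate_cells
    return truth


def _population_layout(truth: GroundTruth) -> dict:
    layout = getattr(truth, "populations", None)
    if layout is None:
        if set(truth.abundance_multiplier.index) == set(DEFAULT_POPULATIONS):
            layout = dict(DEFAULT_POPULATIONS)
        else:
            layout, _ = _generic_populations(truth.lineages)
    return layout


def simulate_cells(
    truth: GroundTruth,
    n_cells_per_timepoint: int = 500,
    timepoints: list[str] | None = None,
    noise_dispersion: float = 10.0,
    seed: int = 0,
) -> ExpressionDataset:
    """Sample cells per timepoint from the planted regulatory model.

    Per timepoint, cells are allocated to populations multinomially with
    probabilities proportional to baseline fraction x abundance
    multiplier.  TF means follow the lineage/pseudotime activation curves,
    target means the clamped-linear GRN link, and counts are drawn
    negative-binomial with shape ``noise_dispersion`` (``np.inf`` =
    Poisson).
    """
    if noise_dispersion <= 0:
        raise ValueError("noise_dispersion must be positive (np.inf for the Poisson limit)")
    if n_cells_per_timepoint < 50:
        raise ValueError("n_cells_per_timepoint must be at least 50")
    rng = np.random.default_rng(seed)
    timepoints = list(timepoints) if timepoints else list(truth.abundance_multiplier.columns)
    layout = _population_layout(truth)
    pops = list(layout)
    base_frac = np.array([layout[p][3] for p in pops])
    lineages = truth.lineages

    rows = []
    for tp in timepoints:
        mult = truth.abundance_multiplier.loc[pops, tp].to_numpy()
        probs = base_frac * mult
        probs = probs / probs.sum()
        alloc = rng.multinomial(n_cells_per_timepoint, probs)
        for pop, n_pop in zip(pops, alloc):
            lin, t_lo, t_hi, _ = layout[pop]
            for _ in range(n_pop):
                lineage = lin if lin is not None else lineages[rng.integers(len(lineages))]
                t = rng.uniform(t_lo, t_hi)
                rows.append((tp, pop, lineage, t))

    n = len(rows)
    timepoint = np.array([r[0] for r in rows], dtype=object)
    population = np.array([r[1] for r in rows], dtype=object)
    lineage = np.array([r[2] for r in rows], dtype=object)
    pt = np.array([r[3] for r in rows], dtype=float)

    tf_names = truth.tfs
    genes = list(truth.grn_weights.columns)
    n_tfs = len(tf_names)
    is_mito = np.array([g.startswith("mt-") for g in genes])
    target_cols = [i for i, g in enumerate(genes) if (g not in tf_names) and not is_mito[i]]

    # TF means: log-normal latent fluctuation + driver ramp on own lineage
    latent = rng.standard_normal((n, n_tfs))
    tf_mean = _TF_BASE_MEAN * np.exp(_TF_LATENT_SD * latent)
    driver_of = {tf: lin for lin, tfs in truth.driver_map.items() for tf in tfs}
    for j, tf in enumerate(tf_names):
        lin = driver_of.get(tf)
        if lin is not None:
            own = lineage == lin
            tf_mean[own, j] += _DRIVER_AMPLITUDE * pt[own]

    w = truth.grn_weights.to_numpy()  # tfs x genes
    mean = np.zeros((n, len(genes)))
    mean[:, :] = _TARGET_BASELINE
    linked = tf_mean @ w  # n x genes
    mean += linked
    np.clip(mean, _TARGET_FLOOR, None, out=mean)
    for j, tf in enumerate(tf_names):
        mean[:, genes.index(tf)] = tf_mean[:, j]
    mean[:, is_mito] = _MITO_MEAN

    if np.isinf(noise_dispersion):
        counts = rng.poisson(mean)
    else:
        r = float(noise_dispersion)
        p = r / (r + mean)
        counts = rng.negative_binomial(r, p)
    counts = counts.astype(np.int64)

    # guard: no zero-total cells (normalization requires positive totals)
    empty = np.flatnonzero(counts.sum(axis=1) == 0)
    for i in empty:
        counts[i, int(np.argmax(mean[i]))] = 1

    # deterministic branch layout + jitter
    ang = {lin: np.deg2rad(_BRANCH_ANGLES.get(lin, 360.0 * k / len(lineages)))
           for k, lin in enumerate(lineages)}
    theta = np.array([ang[l] for l in lineage])
    emb = _EMBED_RADIUS * pt[:, None] * np.stack([np.cos(theta), np.sin(theta)], axis=1)
    emb += rng.normal(scale=_EMBED_JITTER, size=emb.shape)

    cell_meta = pd.DataFrame(
        {
            "cell_id": [f"C{i:06d}" for i in range(n)],
            "sample_id": timepoint,
            "timepoint": timepoint,
            "population": population,
            "lineage": lineage,
            "pseudotime": pt,
        }
    )
    gene_meta = pd.DataFrame({"gene_id": genes, "is_mito": is_mito})
    ds = ExpressionDataset(
        counts=counts, cell_meta=cell_meta, gene_meta=gene_meta, embedding=emb
    )
    ds = lognormalize(ds)
    truth.lineage_of_cell = lineage.copy()
    truth.pseudotime_true = pt.copy()
    return ds


def inject_mito_and_outliers(
    ds: ExpressionDataset,
    frac_low: float = 0.0,
    frac_high: float = 0.0,
    frac_mito: float = 0.0,
    seed: int = 0,
) -> ExpressionDataset:
    """Rewrite a disjoint random subset of cells so each violates exactly
    one QC rule (expressed genes < 500, expressed genes > 5000, or
    mitochondrial UMI fraction > 20%).  Flags land in
    ``cell_meta['qc_violation']``.
    """
    for f in (frac_low, frac_high, frac_mito):
        if not (0 <= f < 1):
            raise ValueError("fractions must lie in [0, 1)")
    if frac_low + frac_high + frac_mito >= 1:
        raise ValueError("violation fractions must sum to less than 1")
    if ds.n_genes < 10:
        raise ValueError("cannot construct QC violations with fewer than 10 genes")

    n = ds.n_cells
    n_low = int(round(frac_low * n))
    n_high = int(round(frac_high * n))
    n_mito = int(round(frac_mito * n))

    out = ds.copy()
    out.cell_meta["qc_violation"] = "none"
    if n_low + n_high + n_mito == 0:
        return out

    if n_high > 0 and ds.n_genes <= 5000:
        raise ValueError(
            "cannot construct high-gene-count violations: the panel has "
            f"{ds.n_genes} genes but the rule requires > 5000 expressed genes"
        )
    is_mito = out.gene_meta["is_mito"].to_numpy(dtype=bool)
    if n_mito > 0 and not is_mito.any():
        raise ValueError("cannot construct mito violations: no mitochondrial genes in panel")

    rng = np.random.default_rng(seed)
    chosen = rng.choice(n, size=n_low + n_high + n_mito, replace=False)
    low_cells = chosen[:n_low]
    high_cells = chosen[n_low : n_low + n_high]
    mito_cells = chosen[n_low + n_high :]

    counts = out.counts
    for i in low_cells:
        # keep the 50 highest-count genes (ties by gene order), zero the rest
        order = np.argsort(-counts[i], kind="stable")
        keep = order[:50]
        row = np.zeros_like(counts[i])
        row[keep] = np.maximum(counts[i, keep], 1)
        counts[i] = row
        out.cell_meta.loc[i, "qc_violation"] = "low_genes"
    for i in high_cells:
        counts[i] = np.maximum(counts[i], 1)  # every gene expressed
        out.cell_meta.loc[i, "qc_violation"] = "high_genes"
    for i in mito_cells:
        non_mito_total = counts[i, ~is_mito].sum()
        per_gene = int(np.ceil(0.5 * max(non_mito_total, 10) / is_mito.sum()))
        counts[i, is_mito] = per_gene  # mito fraction ~1/3 > 20%
        out.cell_meta.loc[i, "qc_violation"] = "mito"

    out.norm = None  # counts changed; the norm layer is stale
    return out


def write_fixture(
    ds: ExpressionDataset,
    truth: GroundTruth | None,
    out_dir: str | Path,
    overwrite: bool = False,
) -> dict[str, Path]:
    """Write the dataset (10x-style MTX + TSVs + CSVs) and the ground truth.

    Files: ``matrix.mtx`` (genes-by-cells, integer), ``features.tsv``,
    ``barcodes.tsv``, ``cell_meta.csv``, ``embedding.csv`` and, when a
    ground truth is given, ``ground_truth.json``.  Round-trips losslessly
    through :func:`scregflow.io.read_matrix`.
    """
    if ds.n_cells == 0:
        raise ValueError("refusing to write a fixture with 0 cells")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} is not empty; pass overwrite=True to replace it")
    out.mkdir(parents=True, exist_ok=True)

    paths = {}
    from scipy.sparse import csr_matrix

    mat = csr_matrix(ds.counts.T.astype(np.int64))  # genes x cells, 10x convention
    paths["matrix"] = out / "matrix.mtx"
    mmwrite(paths["matrix"], mat, field="integer")

    feats = pd.DataFrame(
        {
            "gene_id": ds.gene_meta["gene_id"],
            "gene_name": ds.gene_meta["gene_id"],
            "feature_type": "Gene Expression",
        }
    )
    paths["features"] = out / "features.tsv"
    feats.to_csv(paths["features"], sep="\t", header=False, index=False)

    paths["barcodes"] = out / "barcodes.tsv"
    ds.cell_meta["cell_id"].to_csv(paths["barcodes"], sep="\t", header=False, index=False)

    paths["cell_meta"] = out / "cell_meta.csv"
    ds.cell_meta.to_csv(paths["cell_meta"], index=False)

    paths["embedding"] = out / "embedding.csv"
    pd.DataFrame(ds.embedding, columns=["x", "y"]).assign(
        cell_id=ds.cell_meta["cell_id"].to_numpy()
    )[["cell_id", "x", "y"]].to_csv(paths["embedding"], index=False)

    if truth is not None:
        paths["ground_truth"] = out / "ground_truth.json"
        with open(paths["ground_truth"], "w") as fh:
            json.dump(truth.to_dict(), fh)
    return paths


def default_fixture(
    seed: int = 0,
    n_tfs: int = 9,
    n_targets: int = 180,
    density: float = 0.05,
    n_cells_per_timepoint: int = 500,
    noise_dispersion: float = 10.0,
) -> tuple[ExpressionDataset, GroundTruth]:
    """The study-design-scale synthetic dataset used throughout the tests:
    8 populations, 3 lineages, 6 timepoints, 500 cells per timepoint."""
    truth = simulate_grn(n_tfs=n_tfs, n_targets=n_targets, density=density, seed=seed)
    ds = simulate_cells(
        truth,
        n_cells_per_timepoint=n_cells_per_timepoint,
        noise_dispersion=noise_dispersion,
        seed=seed + 1,
    )
    return ds, truth
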