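"""Graph-diffusion relative-likelihood estimation and response modes.

A kNN cell-cell graph with an adaptive Gaussian kernel carries one-hot
sample indicators; repeated application of the row-stochastic Markov
operator smooths each indicator into a manifold density estimate, and the
per-cell relative likelihood of a post-exposure timepoint versus baseline
is the normalized density ratio l = dens_post / (dens_post + dens_base).
Cells are then classified into down / N.S. / up response modes by the
fixed thresholds l < 0.45 (down) and l > 0.55 (up); a 3-cluster K-means on
l is reported alongside as a concordance diagnostic only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .containers import ExpressionDataset


@dataclass
class CellGraph:
    knn_indices: np.ndarray  # cells x k, no self-loops
    weights: sparse.csr_matrix  # symmetric affinity
    markov: sparse.csr_matrix  # row-stochastic transition matrix
    k: int
    bandwidth_rule: str = "adaptive: distance to the ceil(k/3)-th neighbor"

    @property
    def n_cells(self) -> int:
        return self.knn_indices.shape[0]


@dataclass
class RelativeLikelihood:
    values: np.ndarray  # per-cell l in [0, 1]
    comparison: tuple[str, str]  # (post timepoint, baseline)
    smoothing_steps: int


@dataclass
class ResponseModeTable:
    mode: np.ndarray  # per-cell label in {down, N.S., up}
    thresholds: tuple[float, float] = (0.45, 0.55)
    kmeans_centroids: np.ndarray | None = None  # diagnostic only


def knn_graph(coords: np.ndarray, k: int = 30) -> CellGraph:
    """Adaptive-bandwidth Gaussian kNN affinity graph on raw coordinates.

    The per-cell bandwidth is the distance to the ceil(k/3)-th nearest
    neighbor; affinities w_ij = exp(-(d_ij / sigma_i)^2) on the kNN edges
    are symmetrized by averaging and row-normalized into the Markov
    operator.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dist, idx = nn.kneighbors(coords)
    # drop the self column (guard against duplicate points putting self later)
    self_pos = np.argmax(idx == np.arange(n)[:, None], axis=1)
    keep = np.ones_like(idx, dtype=bool)
    keep[np.arange(n), self_pos] = False
    idx = idx[keep].reshape(n, k)
    dist = dist[keep].reshape(n, k)

    adaptive = int(np.ceil(k / 3)) - 1  # 0-based position of the ceil(k/3)-th neighbor
    sigma = dist[:, adaptive].copy()
    # duplicates can give zero bandwidth; fall back to the nearest positive distance
    bad = sigma <= 0
    if bad.any():
        pos = np.where(dist > 0, dist, np.inf).min(axis=1)
        sigma[bad] = np.where(np.isfinite(pos[bad]), pos[bad], 1e-12)

    aff = np.exp(-((dist / sigma[:, None]) ** 2))
    rows = np.repeat(np.arange(n), k)
    w = sparse.csr_matrix((aff.ravel(), (rows, idx.ravel())), shape=(n, n))
    w = (w + w.T) * 0.5
    deg = np.asarray(w.sum(axis=1)).ravel()
    markov = sparse.diags(1.0 / deg) @ w
    return CellGraph(knn_indices=idx, weights=w.tocsr(), markov=markov.tocsr(), k=k)


def build_graph(
    ds: ExpressionDataset,
    k: int = 30,
    n_pcs: int = 30,
    representation: str = "embedding",
) -> CellGraph:
    """kNN graph on the 2-D embedding or on PCA of the normalized layer."""
    if representation == "embedding":
        coords = ds.embedding
    elif representation == "pca":
        if ds.norm is None:
            raise ValueError("pca representation requires the normalized layer")
        n_comp = min(n_pcs, ds.n_genes, ds.n_cells - 1)
        coords = PCA(n_components=n_comp, random_state=0).fit_transform(ds.norm)
    else:
        raise ValueError(f"unknown representation {representation!r}")
    return knn_graph(coords, k=k)


def relative_likelihood(
    graph: CellGraph,
    sample_of_cell: np.ndarray,
    post: str,
    baseline: str,
    smoothing_steps: int = 10,
) -> RelativeLikelihood:
    """Per-cell relative likelihood of ``post`` versus ``baseline``.

    One-hot sample indicators are diffused ``smoothing_steps`` times with
    the Markov operator, each normalized to a density summing to 1 over
    cells; l_i = dens_post(i) / (dens_post(i) + dens_base(i)), with cells
    where both densities vanish set to the neutral 0.5.
    """
    if post == baseline:
        raise ValueError("post and baseline labels must differ")
    sample_of_cell = np.asarray(sample_of_cell)
    s_post = (sample_of_cell == post).astype(float)
    s_base = (sample_of_cell == baseline).astype(float)
    if s_post.sum() == 0:
        raise ValueError(f"no cells with sample label {post!r}")
    if s_base.sum() == 0:
        raise ValueError(f"no cells with sample label {baseline!r}")
    if smoothing_steps < 0:
        raise ValueError("smoothing_steps must be non-negative")

    for _ in range(smoothing_steps):
        s_post = graph.markov @ s_post
        s_base = graph.markov @ s_base
    dens_post = s_post / s_post.sum()
    dens_base = s_base / s_base.sum()

    tot = dens_post + dens_base
    values = np.full(graph.n_cells, 0.5)
    ok = tot > 1e-12
    values[ok] = dens_post[ok] / tot[ok]
    return RelativeLikelihood(
        values=values, comparison=(post, baseline), smoothing_steps=smoothing_steps
    )


def assign_response_modes(
    rl: RelativeLikelihood,
    t_down: float = 0.45,
    t_up: float = 0.55,
    seed: int = 0,
) -> ResponseModeTable:
    """Threshold rule: l < t_down -> down, l > t_up -> up, else N.S.

    The fixed thresholds are authoritative for the labels; a seeded
    3-cluster K-means on l is fitted and its ordered centroids attached as
    a diagnostic concordance check.
    """
    if t_down >= t_up:
        raise ValueError(f"t_down ({t_down}) must be smaller than t_up ({t_up})")
    values = np.asarray(rl.values, dtype=float)
    if values.min() < 0 or values.max() > 1:
        raise ValueError("relative likelihood values must lie in [0, 1]")
    mode = np.where(values < t_down, "down", np.where(values > t_up, "up", "N.S."))

    centroids = None
    if np.unique(values).size >= 3:
        from sklearn.cluster import KMeans

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            km = KMeans(n_clusters=3, n_init=10, random_state=seed).fit(values[:, None])
        centroids = np.sort(km.cluster_centers_.ravel())
    return ResponseModeTable(
        mode=mode.astype(object), thresholds=(t_down, t_up), kmeans_centroids=centroids
    )


def summarize_modes(
    modes: ResponseModeTable,
    population: np.ndarray,
    timepoint: np.ndarray,
) -> pd.DataFrame:
    """Fractions of down / N.S. / up per (population, timepoint) stratum."""
    population = np.asarray(population)
    timepoint = np.asarray(timepoint)
    if len(population) != len(modes.mode) or len(timepoint) != len(modes.mode):
        raise ValueError("population/timepoint labels must align with cells")
    df = pd.DataFrame(
        {"population": population, "timepoint": timepoint, "mode": modes.mode}
    )
    tab = (
        df.groupby(["population", "timepoint"], observed=True)["mode"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
    )
    for col in ("down", "N.S.", "up"):
        if col not in tab.columns:
            tab[col] = 0.0
    return tab[["down", "N.S.", "up"]].reset_index()
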