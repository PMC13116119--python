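"""Regulon inference, per-cell activity (AUC), specificity and export.

A regulon is a TF together with its inferred target genes.  Targets are
found by ridge-regressing every non-TF gene on the standardized TF
expression panel and keeping edges whose standardized-coefficient
magnitude clears a threshold (optionally intersected with a prior edge
mask).  Per-cell activity is the area under the recovery curve of the
regulon's genes within the top fraction of each cell's expression ranking
(the AUCell statistic); specificity against a cell-type labelling is
RSS = 1 - sqrt(JSD) with the base-2 Jensen-Shannon divergence.  Edge sets
can be sharpened with a per-regulon Gaussian-mixture filter on weight
magnitudes, and networks exported as GraphML or SIF.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .containers import ExpressionDataset
from .preprocessing import zscore_genes


@dataclass
class RegulonSet:
    """Mapping TF -> list of (target gene, weight)."""

    regulons: dict[str, list[tuple[str, float]]]
    provenance: str = "inferred"  # {inferred, prior, ground_truth}

    def __post_init__(self) -> None:
        for tf, targets in self.regulons.items():
            if not targets:
                raise ValueError(f"regulon {tf!r} is empty")
            for g, w in targets:
                if g == tf:
                    raise ValueError(f"regulon {tf!r} targets itself")
                if not np.isfinite(w):
                    raise ValueError(f"non-finite weight on edge {tf}->{g}")

    @property
    def tfs(self) -> list[str]:
        return list(self.regulons)

    def targets_of(self, tf: str) -> list[str]:
        return [g for g, _ in self.regulons[tf]]

    def to_frame(self) -> pd.DataFrame:
        rows = [(tf, g, w) for tf, tg in self.regulons.items() for g, w in tg]
        return pd.DataFrame(rows, columns=["tf", "target", "weight"])

    @classmethod
    def from_ground_truth(cls, truth) -> "RegulonSet":
        regs = {}
        for tf in truth.tfs:
            row = truth.grn_weights.loc[tf]
            targets = [(g, float(w)) for g, w in row.items() if w != 0 and g != tf]
            if targets:
                regs[tf] = targets
        return cls(regulons=regs, provenance="ground_truth")


@dataclass
class ActivityMatrix:
    auc: pd.DataFrame  # cells x regulons, values in [0, 1]
    top_frac: float
    zauc: pd.DataFrame = field(init=False)  # per-regulon z-scored AUC

    def __post_init__(self) -> None:
        a = self.auc.to_numpy()
        if a.size and (a.min() < -1e-12 or a.max() > 1 + 1e-12):
            raise ValueError("AUC values must lie in [0, 1]")
        self.zauc = pd.DataFrame(
            zscore_genes(a), index=self.auc.index, columns=self.auc.columns
        )


@dataclass
class RSSMatrix:
    rss: pd.DataFrame  # cell types x regulons, values in [0, 1]


def importance_matrix(
    ds: ExpressionDataset,
    tf_list: list[str],
    ridge_alpha: float = 1.0,
) -> pd.DataFrame:
    """Standardized ridge coefficients of every non-TF gene on all TFs.

    Rows are TFs, columns non-TF genes; the entries are the (signed)
    coefficients of the per-gene ridge fit on z-scored expression, whose
    magnitudes serve as edge importances.
    """
    if not tf_list:
        raise ValueError("tf_list must not be empty")
    if ds.norm is None:
        raise ValueError("dataset needs a normalized layer (run lognormalize first)")
    tf_idx = ds.gene_index(tf_list)
    other = [g for g in ds.genes if g not in set(tf_list)]
    other_idx = ds.gene_index(other)

    X = zscore_genes(ds.norm[:, tf_idx])
    Y = zscore_genes(ds.norm[:, other_idx])
    n_tf = X.shape[1]
    gram = X.T @ X + ridge_alpha * np.eye(n_tf)
    beta = np.linalg.solve(gram, X.T @ Y)  # tfs x genes
    return pd.DataFrame(beta, index=list(tf_list), columns=other)


def infer_modules(
    ds: ExpressionDataset,
    tf_list: list[str],
    prior_edges: pd.DataFrame | set | None = None,
    min_importance: float = 0.1,
    ridge_alpha: float = 1.0,
) -> RegulonSet:
    """Build regulons from standardized ridge importances.

    An edge TF->gene is kept when |standardized coefficient| >=
    ``min_importance`` and, if ``prior_edges`` is given (a boolean
    TF-by-gene frame or a set of (tf, gene) pairs), when the prior allows
    it.  TFs left without any retained target are dropped with a warning.
    """
    beta = importance_matrix(ds, tf_list, ridge_alpha=ridge_alpha)
    regs: dict[str, list[tuple[str, float]]] = {}
    for tf in beta.index:
        row = beta.loc[tf]
        kept = row[row.abs() >= min_importance]
        if prior_edges is not None:
            if isinstance(prior_edges, pd.DataFrame):
                allowed = {g for g in kept.index if g in prior_edges.columns
                           and tf in prior_edges.index and bool(prior_edges.loc[tf, g])}
            else:
                allowed = {g for g in kept.index if (tf, g) in prior_edges}
            kept = kept[kept.index.isin(allowed)]
        if len(kept) == 0:
            warnings.warn(f"TF {tf!r} has an empty regulon and is dropped", stacklevel=2)
            continue
        regs[tf] = [(g, float(w)) for g, w in kept.items()]
    return RegulonSet(regulons=regs, provenance="inferred")


def aucell_scores(
    ds: ExpressionDataset,
    regs: RegulonSet,
    top_frac: float = 0.05,
) -> ActivityMatrix:
    """Per-cell recovery-curve AUC of each regulon's genes.

    Genes are ranked per cell by normalized expression, descending, ties
    broken by fixed gene order.  With cutoff = ceil(top_frac * n_genes)
    and hits(r) = number of regulon genes at rank <= r,

        AUC = sum_{r=1..cutoff} hits(r) / (m * cutoff),

    where m is the regulon size within the dataset's gene universe.  A
    regulon whose genes all sit at the very top of a ranking attains the
    maximum 1 - (m - 1) / (2 * cutoff); a regulon entirely outside the
    cutoff scores 0.
    """
    if not (0 < top_frac < 1):
        raise ValueError("top_frac must lie in (0, 1)")
    if ds.norm is None:
        raise ValueError("dataset needs a normalized layer (run lognormalize first)")
    n_cells, n_genes = ds.norm.shape
    cutoff = math.ceil(top_frac * n_genes)

    # ranks[i, g] = 1-based rank of gene g in cell i (stable => gene-order ties)
    order = np.argsort(-ds.norm, axis=1, kind="stable")
    ranks = np.empty((n_cells, n_genes), dtype=np.int64)
    np.put_along_axis(ranks, order, np.arange(1, n_genes + 1)[None, :], axis=1)

    cols = {}
    for tf, targets in regs.regulons.items():
        members = [g for g, _ in targets if g in ds.genes]
        if not members:
            raise ValueError(f"regulon {tf!r} has no genes in the dataset")
        m = len(members)
        if m > cutoff:
            warnings.warn(
                f"regulon {tf!r} ({m} genes) exceeds the rank cutoff ({cutoff}); "
                "its AUC cannot reach the top of the scale",
                stacklevel=2,
            )
        member_ranks = ranks[:, ds.gene_index(members)]
        contrib = np.clip(cutoff - member_ranks + 1, 0, None).sum(axis=1)
        cols[tf] = contrib / (m * cutoff)
    auc = pd.DataFrame(cols, index=ds.cell_ids)
    return ActivityMatrix(auc=auc, top_frac=top_frac)


def regulon_specificity(act: ActivityMatrix, cell_type: np.ndarray) -> RSSMatrix:
    """RSS = 1 - sqrt(JSD_2) between normalized activity and type indicator.

    JSD is the base-2 Jensen-Shannon divergence (in [0, 1]); RSS is 1 when
    the normalized activity distribution equals the normalized indicator
    and 0 when their supports are disjoint.
    """
    cell_type = np.asarray(cell_type)
    types = sorted(pd.unique(cell_type).tolist())
    if len(types) < 2:
        raise ValueError("regulon specificity needs at least 2 cell types")
    out = pd.DataFrame(index=types, columns=act.auc.columns, dtype=float)
    for reg in act.auc.columns:
        a = act.auc[reg].to_numpy(dtype=float)
        s = a.sum()
        if s <= 0:
            raise ValueError(f"regulon {reg!r} has all-zero activity; RSS undefined")
        p_r = a / s
        for t in types:
            ind = (cell_type == t).astype(float)
            p_c = ind / ind.sum()
            dist = jensenshannon(p_r, p_c, base=2)  # sqrt of the base-2 JSD
            out.loc[t, reg] = float(np.clip(1.0 - dist, 0.0, 1.0))
    return RSSMatrix(rss=out)


def select_markers(rss: RSSMatrix, n_top: int = 10) -> dict[str, list[str]]:
    """Top ``n_top`` regulons per cell type by descending RSS (ties broken
    lexicographically by TF name)."""
    if n_top > rss.rss.shape[1]:
        raise ValueError(f"n_top={n_top} exceeds the number of regulons ({rss.rss.shape[1]})")
    markers = {}
    for t in rss.rss.index:
        row = rss.rss.loc[t]
        ordered = sorted(row.index, key=lambda tf: (-row[tf], tf))
        markers[t] = ordered[:n_top]
    return markers


def filter_edges_gmm(
    regs: RegulonSet,
    tf: str,
    n_components: int = 2,
    seed: int = 0,
) -> list[tuple[str, float]]:
    """Keep a regulon's edges assigned to the highest-mean weight component.

    A Gaussian mixture is fitted to the |weight| values; edges with
    posterior probability > 0.5 of membership in the highest-mean
    component are retained.  Zero-variance weights are a degenerate fit:
    every edge is retained with a warning.
    """
    edges = regs.regulons[tf]
    if len(edges) < 2 * n_components:
        raise ValueError(
            f"regulon {tf!r} has {len(edges)} edges; need at least {2 * n_components}"
        )
    w = np.abs(np.array([abs(x[1]) for x in edges], dtype=float))
    if np.ptp(w) < 1e-12:
        warnings.warn(
            f"regulon {tf!r} has (near-)identical weights; retaining all edges",
            stacklevel=2,
        )
        return list(edges)
    from sklearn.mixture import GaussianMixture

    gm = GaussianMixture(n_components=n_components, random_state=seed, n_init=3)
    gm.fit(w[:, None])
    top = int(np.argmax(gm.means_.ravel()))
    post = gm.predict_proba(w[:, None])[:, top]
    return [e for e, p in zip(edges, post) if p > 0.5]


def export_network(
    regs: RegulonSet,
    markers: dict[str, list[str]] | None,
    act: ActivityMatrix | None,
    path: str | Path,
    format: str = "graphml",
) -> Path:
    """Write the (marker-restricted) regulon graph as GraphML or SIF.

    Nodes carry a ``role`` attribute (tf / target) and, for TFs with
    activity available, their mean z-scored AUC; edges are directed and
    weighted.
    """
    import networkx as nx

    if markers is not None:
        wanted = {tf for tfs in markers.values() for tf in tfs}
        unknown = wanted - set(regs.regulons)
        if unknown:
            raise ValueError(f"marker TFs not in the regulon set: {sorted(unknown)}")
    else:
        wanted = set(regs.regulons)

    g = nx.DiGraph()
    for tf in sorted(wanted):
        mean_zauc = 0.0
        if act is not None and tf in act.zauc.columns:
            mean_zauc = float(act.zauc[tf].mean())
        g.add_node(tf, role="tf", mean_zauc=mean_zauc)
        for target, w in regs.regulons[tf]:
            if not g.has_node(target):
                g.add_node(target, role="target")
            g.add_edge(tf, target, weight=float(w))

    path = Path(path)
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "sif":
        with open(path, "w") as fh:
            for u, v in g.edges:
                fh.write(f"{u} regulates {v}\n")
    else:
        raise ValueError(f"unknown export format {format!r} (use 'graphml' or 'sif')")
    return path
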