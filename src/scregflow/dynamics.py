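"""Adaptive sliding-window smoothing of TF activity along pseudotime.

Cells are ordered by lineage-wise min-max-normalized pseudotime and
partitioned into overlapping windows of a fixed cell count (default 300).
The step between consecutive window starts is nominally 100 cells but is
adapted so that the pseudotime distance between consecutive window start
cells stays within a fixed interval (default 0.03-0.06): through dense
stretches the step inflates to clear the lower bound, through sparse
stretches it shrinks (to a minimum of one cell) to respect the upper
bound.  Per window, the mean z-scored activity of each TF and the mean
pseudotime are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regulons import RSSMatrix


@dataclass
class DynamicActivity:
    """Windows-by-TF smoothed activity along one lineage."""

    window_means: pd.DataFrame  # windows x TFs, mean zAUC
    window_pseudotime: np.ndarray  # mean normalized pseudotime per window
    window_start_pt: np.ndarray  # pseudotime of each window's start cell
    step_cells: np.ndarray  # realized step sizes (cells), len = n_windows - 1
    window_size: int
    interval: tuple[float, float]
    lineage: str | None = None
    condition: str | None = None

    @property
    def n_windows(self) -> int:
        return len(self.window_means)

    def to_long(self) -> pd.DataFrame:
        df = self.window_means.copy()
        df.insert(0, "window", np.arange(self.n_windows))
        df.insert(1, "pseudotime", self.window_pseudotime)
        long = df.melt(
            id_vars=["window", "pseudotime"], var_name="tf", value_name="mean_zauc"
        )
        long.insert(0, "lineage", self.lineage)
        long.insert(1, "condition", self.condition)
        return long


def normalize_pseudotime(pt: np.ndarray, scope: np.ndarray | None = None) -> np.ndarray:
    """Min-max scale pseudotime to [0, 1], independently per lineage."""
    pt = np.asarray(pt, dtype=float)
    out = np.empty_like(pt)
    groups = np.zeros(len(pt), dtype=object) if scope is None else np.asarray(scope)
    for g in pd.unique(groups):
        m = groups == g
        lo, hi = pt[m].min(), pt[m].max()
        if hi <= lo:
            raise ValueError(f"pseudotime is constant within lineage {g!r}")
        out[m] = (pt[m] - lo) / (hi - lo)
    return out


def sliding_window_activity(
    zauc: pd.DataFrame,
    pt_norm: np.ndarray,
    window: int = 300,
    step0: int = 100,
    interval: tuple[float, float] = (0.03, 0.06),
    lineage: str | None = None,
    condition: str | None = None,
) -> DynamicActivity:
    """Window means of activity with a density/pseudotime-adaptive step.

    From a window starting at sorted index i, the candidate step is
    ``step0`` cells; if the pseudotime distance to the candidate next
    start is below ``interval[0]`` the step is increased to the smallest
    one clearing it, and if above ``interval[1]`` decreased to the largest
    one (at least 1 cell) respecting it.  Iteration stops when a full
    window no longer fits.
    """
    d_min, d_max = interval
    if not (0 < d_min < d_max):
        raise ValueError("interval must satisfy 0 < d_min < d_max")
    if window < 1 or step0 < 1:
        raise ValueError("window and step0 must be positive")
    pt_norm = np.asarray(pt_norm, dtype=float)
    n = len(pt_norm)
    if n < window:
        raise ValueError(
            f"{n} cells but window={window}; use a smaller window for this lineage"
        )
    if len(zauc) != n:
        raise ValueError("zauc rows must align with pt_norm")

    order = np.argsort(pt_norm, kind="stable")
    pt_s = pt_norm[order]
    z_s = zauc.to_numpy()[order]

    starts = [0]
    steps: list[int] = []
    i = 0
    while True:
        s = min(step0, n - 1 - i)
        if s < 1:
            break
        d = pt_s[i + s] - pt_s[i]
        if d < d_min:
            j = int(np.searchsorted(pt_s, pt_s[i] + d_min, side="left"))
            if j > n - 1:
                break  # no feasible step clears d_min before the tail
            s = j - i
        elif d > d_max:
            j = int(np.searchsorted(pt_s, pt_s[i] + d_max, side="right")) - 1
            s = max(j - i, 1)  # single-cell fallback when even s=1 overshoots
        nxt = i + s
        if nxt + window > n:
            break
        starts.append(nxt)
        steps.append(s)
        i = nxt

    starts_arr = np.asarray(starts)
    means = np.stack([z_s[st : st + window].mean(axis=0) for st in starts_arr])
    wpt = np.array([pt_s[st : st + window].mean() for st in starts_arr])
    return DynamicActivity(
        window_means=pd.DataFrame(means, columns=zauc.columns),
        window_pseudotime=wpt,
        window_start_pt=pt_s[starts_arr],
        step_cells=np.asarray(steps, dtype=int),
        window_size=window,
        interval=(d_min, d_max),
        lineage=lineage,
        condition=condition,
    )


def select_lineage_tfs(
    rss: RSSMatrix,
    lineage_types: list[str],
    n_top: int = 30,
) -> list[str]:
    """Top TFs ranked by the maximum RSS over a lineage's cell types
    (e.g. GM = {MPP3, GMP}); ties broken lexicographically."""
    if not lineage_types:
        raise ValueError("lineage_types must not be empty")
    missing = [t for t in lineage_types if t not in rss.rss.index]
    if missing:
        raise ValueError(f"cell types not in the RSS matrix: {missing}")
    score = rss.rss.loc[lineage_types].max(axis=0)
    ordered = sorted(score.index, key=lambda tf: (-score[tf], tf))
    return ordered[: min(n_top, len(ordered))]


def compare_conditions(
    da_a: DynamicActivity,
    da_b: DynamicActivity,
    tf: str,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Window series of one TF under two conditions of the same lineage.

    Windows are reported as-is on their own pseudotime coordinates (no
    interpolation); the summary holds each condition's overall mean and
    the difference a - b.
    """
    if da_a.lineage != da_b.lineage:
        raise ValueError(
            f"lineage mismatch: {da_a.lineage!r} vs {da_b.lineage!r}"
        )
    for da in (da_a, da_b):
        if tf not in da.window_means.columns:
            raise KeyError(f"TF {tf!r} missing from condition {da.condition!r}")
    rows = []
    for da in (da_a, da_b):
        for w in range(da.n_windows):
            rows.append(
                {
                    "condition": da.condition,
                    "window": w,
                    "pseudotime": da.window_pseudotime[w],
                    "activity": da.window_means[tf].iloc[w],
                }
            )
    table = pd.DataFrame(rows)
    mean_a = float(da_a.window_means[tf].mean())
    mean_b = float(da_b.window_means[tf].mean())
    summary = {"mean_a": mean_a, "mean_b": mean_b, "mean_difference": mean_a - mean_b}
    return table, summary
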