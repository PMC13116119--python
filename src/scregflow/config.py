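"""Pipeline configuration and the end-to-end orchestrator.

Stage defaults follow the published rules wherever the source protocol
states one: QC at 500/5000 expressed genes and 20% mitochondrial UMIs,
response-mode thresholds 0.45/0.55, top-10 marker regulons, top-30
lineage TFs, windows of 300 cells with initial step 100 and pseudotime
interval 0.03-0.06, and the lineage definitions ME:{MPP2, MEP},
GM:{MPP3, GMP}, LY:{MPP4, CLP}.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("scregflow")

DEFAULT_LINEAGE_TYPES = {
    "ME": ["MPP2", "MEP"],
    "GM": ["MPP3", "GMP"],
    "LY": ["MPP4", "CLP"],
}


@dataclass
class PipelineConfig:
    # simulation
    n_tfs: int = 9
    n_targets: int = 180
    density: float = 0.05
    n_cells_per_timepoint: int = 500
    noise_dispersion: float = 10.0
    # QC
    min_genes: int = 500
    max_genes: int = 5000
    max_mito_frac: float = 0.20
    # graph / abundance
    k: int = 30
    n_pcs: int = 30
    representation: str = "embedding"
    smoothing_steps: int = 10
    t_down: float = 0.45
    t_up: float = 0.55
    baseline: str = "D0"
    # regulons
    top_frac: float = 0.05
    min_importance: float = 0.1
    n_top_markers: int = 10
    # dynamics
    n_top_lineage_tfs: int = 30
    window: int = 300
    step0: int = 100
    d_min: float = 0.03
    d_max: float = 0.06
    # perturbation
    grid_bins: int = 40
    ridge_alpha: float = 1.0
    n_propagation: int = 3
    kernel_scale: float = 0.05
    # enrichment
    n_perm: int = 1000
    # misc
    seed: int = 0
    lineage_types: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_LINEAGE_TYPES.items()}
    )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        filled = cls(**d)
        for name in known - set(d):
            logger.info("config: %s filled with default %r", name, getattr(filled, name))
        return validate_config(filled)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_config(config: PipelineConfig) -> PipelineConfig:
    """Range-check every stage parameter; raises on the first violation."""
    c = config
    for name in ("n_tfs", "n_targets", "n_cells_per_timepoint", "k", "n_pcs",
                 "smoothing_steps", "n_top_markers", "n_top_lineage_tfs",
                 "window", "step0", "grid_bins", "n_propagation", "n_perm"):
        v = getattr(c, name)
        if not isinstance(v, (int, np.integer)) or v < 1:
            raise ValueError(f"config {name} must be a positive integer, got {v!r}")
    for name in ("density", "max_mito_frac", "top_frac"):
        v = getattr(c, name)
        if not (0 <= v <= 1):
            raise ValueError(f"config {name} must lie in [0, 1], got {v!r}")
    if c.noise_dispersion <= 0:
        raise ValueError("config noise_dispersion must be positive")
    if not (0 < c.d_min < c.d_max):
        raise ValueError(f"config interval must satisfy 0 < d_min < d_max, got ({c.d_min}, {c.d_max})")
    if not (0 <= c.t_down < c.t_up <= 1):
        raise ValueError(f"config thresholds must satisfy 0 <= t_down < t_up <= 1, got ({c.t_down}, {c.t_up})")
    if c.min_genes < 0 or c.max_genes < c.min_genes:
        raise ValueError("config QC gene thresholds must satisfy 0 <= min_genes <= max_genes")
    if c.ridge_alpha <= 0 or c.kernel_scale <= 0:
        raise ValueError("config ridge_alpha and kernel_scale must be positive")
    if c.representation not in ("embedding", "pca"):
        raise ValueError("config representation must be 'embedding' or 'pca'")
    return c


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Simulate -> QC -> normalize -> graph -> abundance -> regulons ->
    dynamics -> perturbation, writing every intermediate artifact plus a
    manifest recording parameters and seeds."""
    from . import __version__
    from . import abundance as ab
    from . import dynamics as dyn
    from . import perturbation as pert
    from . import preprocessing as pp
    from . import regulons as reg
    from . import synthetic as syn

    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": config.to_dict(), "stages": {}}
    bundle: dict = {}
    stage = "simulate"
    try:
        truth = syn.simulate_grn(
            n_tfs=config.n_tfs, n_targets=config.n_targets,
            density=config.density, seed=config.seed,
        )
        ds = syn.simulate_cells(
            truth,
            n_cells_per_timepoint=config.n_cells_per_timepoint,
            noise_dispersion=config.noise_dispersion,
            seed=config.seed + 1,
        )
        manifest["stages"][stage] = {"n_cells": ds.n_cells, "n_genes": ds.n_genes}
        logger.info("simulate: %d cells x %d genes", ds.n_cells, ds.n_genes)

        stage = "qc"
        ds, qc_report = pp.filter_cells(
            ds, min_genes=config.min_genes, max_genes=config.max_genes,
            max_mito_frac=config.max_mito_frac,
        )
        (out / "qc_report.json").write_text(qc_report.to_json())
        manifest["stages"][stage] = {"n_retained": qc_report.n_retained}
        logger.info("qc: retained %d/%d cells", qc_report.n_retained, qc_report.n_input_cells)

        stage = "normalize"
        ds = pp.lognormalize(ds)
        manifest["stages"][stage] = {"shape": list(ds.norm.shape)}

        stage = "graph"
        graph = ab.build_graph(ds, k=config.k, n_pcs=config.n_pcs,
                               representation=config.representation)
        manifest["stages"][stage] = {"k": config.k}

        stage = "abundance"
        timepoints = [t for t in pd.unique(ds.cell_meta["timepoint"]) if t != config.baseline]
        samples = ds.cell_meta["sample_id"].to_numpy()
        mode_frames = []
        for tp in timepoints:
            rl = ab.relative_likelihood(
                graph, samples, post=tp, baseline=config.baseline,
                smoothing_steps=config.smoothing_steps,
            )
            modes = ab.assign_response_modes(rl, t_down=config.t_down,
                                             t_up=config.t_up, seed=config.seed)
            per_cell = pd.DataFrame(
                {"cell_id": ds.cell_ids, "timepoint_vs_baseline": tp,
                 "likelihood": rl.values, "mode": modes.mode}
            )
            per_cell.to_csv(out / f"likelihood_{tp}.csv", index=False)
            props = ab.summarize_modes(
                modes, ds.cell_meta["population"].to_numpy(),
                np.full(ds.n_cells, tp),
            )
            mode_frames.append(props)
        pd.concat(mode_frames).to_csv(out / "response_modes.csv", index=False)
        manifest["stages"][stage] = {"comparisons": list(map(str, timepoints))}

        stage = "regulons"
        tf_list = [g for g in ds.genes if g.startswith("Tf")]
        regset = reg.infer_modules(ds, tf_list, min_importance=config.min_importance)
        regset.to_frame().to_csv(out / "regulons.tsv", sep="\t", index=False)
        act = reg.aucell_scores(ds, regset, top_frac=config.top_frac)
        dead = act.auc.columns[(act.auc.sum(axis=0) == 0)]
        if len(dead):
            # regulons whose genes never reach the rank cutoff carry no
            # activity signal; RSS is undefined for them
            logger.warning("dropping %d all-zero-activity regulons: %s",
                           len(dead), list(dead))
            regset = reg.RegulonSet(
                {tf: tg for tf, tg in regset.regulons.items() if tf not in set(dead)},
                provenance=regset.provenance,
            )
            act = reg.ActivityMatrix(auc=act.auc.drop(columns=dead),
                                     top_frac=act.top_frac)
        act.auc.to_csv(out / "auc.csv")
        rss = reg.regulon_specificity(act, ds.cell_meta["population"].to_numpy())
        rss.rss.to_csv(out / "rss.csv")
        n_top = min(config.n_top_markers, rss.rss.shape[1])
        markers = reg.select_markers(rss, n_top=n_top)
        (out / "markers.json").write_text(json.dumps(markers, indent=2))
        reg.export_network(regset, markers, act, out / "network.graphml", format="graphml")
        manifest["stages"][stage] = {"n_regulons": len(regset.regulons), "n_top_markers": n_top}
        logger.info("regulons: %d regulons scored on %d cells", len(regset.regulons), ds.n_cells)

        stage = "dynamics"
        dyn_tables = []
        for lin, types in config.lineage_types.items():
            in_lin = ds.cell_meta["lineage"].to_numpy() == lin
            if in_lin.sum() < config.window:
                logger.warning("lineage %s has %d cells (< window); skipped", lin, in_lin.sum())
                continue
            pt = ds.cell_meta["pseudotime"].to_numpy()[in_lin]
            pt_norm = dyn.normalize_pseudotime(pt)
            da = dyn.sliding_window_activity(
                act.zauc.iloc[in_lin], pt_norm, window=config.window,
                step0=config.step0, interval=(config.d_min, config.d_max),
                lineage=lin, condition="all",
            )
            dyn_tables.append(da.to_long())
        if dyn_tables:
            pd.concat(dyn_tables).to_csv(out / "dynamic_activity.csv", index=False)
        manifest["stages"][stage] = {"lineages": len(dyn_tables)}

        stage = "perturbation"
        grn = pert.fit_linear_grn(ds, regset, ridge_alpha=config.ridge_alpha)
        dev = pert.development_flow(ds, grid_bins=config.grid_bins)
        ps_rows = []
        for lin, drivers in truth.driver_map.items():
            for tf in drivers:
                if tf not in grn.genes:
                    continue
                for mode in ("KI", "KO"):
                    spec = (
                        pert.PerturbationSpec.knockin(tf, ds, n_propagation=config.n_propagation)
                        if mode == "KI"
                        else pert.PerturbationSpec.knockout(tf, n_propagation=config.n_propagation)
                    )
                    ff = pert.perturb_and_score(
                        ds, grn, spec, graph, dev=dev, kernel_scale=config.kernel_scale
                    )
                    for target_lin, ps in ff.ps_per_lineage.items():
                        ps_rows.append(
                            {"tf": tf, "mode": mode, "timepoint": "all",
                             "lineage": target_lin, "ps": ps}
                        )
        ps_table = pd.DataFrame(ps_rows)
        ps_table.to_csv(out / "perturbation_scores.csv", index=False)
        manifest["stages"][stage] = {"n_perturbations": int(len(ps_rows))}
        logger.info("perturbation: %d (tf, mode, lineage) scores", len(ps_rows))

        bundle = {
            "dataset": ds, "truth": truth, "qc_report": qc_report, "graph": graph,
            "regulons": regset, "activity": act, "rss": rss, "markers": markers,
            "ps_table": ps_table,
        }
    except Exception as err:
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    bundle["manifest"] = manifest
    return bundle
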