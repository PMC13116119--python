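# scregflow

Single-cell regulatory dynamics after acute injury: who expands, which
transcription factors (TFs) drive it, and what happens if you force a TF
on or off.

`scregflow` re-implements, as a tested and reusable pipeline, an
integrative workflow for irradiation-injured hematopoietic stem and
progenitor cells (HSPCs) profiled by scRNA-seq over a baseline (D0) and
five recovery timepoints. It is aimed at computational biologists who
want the individual algorithmic stages as transparent, testable library
functions rather than a chain of heavyweight external tools. Every stage
runs end-to-end on seeded synthetic data with a known ground-truth gene
regulatory network (GRN), so every claim the pipeline makes can be checked
against planted truth.

## What it computes

- **Abundance response modes.** On a kNN cell-cell graph with an adaptive
  Gaussian kernel, one-hot sample indicators are diffused by a
  row-stochastic Markov operator into density estimates; the per-cell
  relative likelihood of a post-exposure timepoint versus baseline is
  `ℓ = dens_post / (dens_post + dens_base)`. Cells with `ℓ < 0.45` are
  "down", `ℓ > 0.55` "up", otherwise "N.S.".
- **Regulons and activity.** TF→target modules from standardized ridge
  importances (optionally masked by prior edges); per-cell activity as the
  AUCell recovery-curve AUC over the top 5% of each cell's expression
  ranking; regulon specificity `RSS = 1 − sqrt(JSD₂)` against cell-type
  indicators; top-10 markers per type; per-regulon Gaussian-mixture edge
  filtering; GraphML/SIF export.
- **Dynamic TF activity.** Along each lineage (ME, GM, LY), min–max
  normalized pseudotime; sliding windows of 300 cells whose step starts at
  100 cells and adapts so consecutive window starts are 0.03–0.06 apart in
  pseudotime; per-window mean z-scored activity.
- **Gene-set scoring.** A rank-based single-sample enrichment score per
  cell with population/timepoint z-summaries, and preranked GSEA
  (weighted-KS ES, gene-permutation null, BH-FDR).
- **In-silico perturbation.** A linear GRN (per-population ridge fits on
  allowed edges) propagates the shift from pinning one TF — knock-out at
  0, knock-in at `max(1, 2 × 95th percentile)` of its observed expression.
  The shift is projected into the embedding as a flow field; the
  developmental flow is the gradient of kernel-smoothed pseudotime, and
  the perturbation score `PS = ⟨perturbed flow, developmental flow⟩`
  averaged per lineage. `PS > 0`: the perturbation promotes
  differentiation along that lineage.

## Worked example

```python
import scregflow as sf

ds, truth = sf.default_fixture(seed=0, n_cells_per_timepoint=334)

graph = sf.build_graph(ds, k=30)
rl = sf.relative_likelihood(graph, ds.cell_meta["sample_id"].to_numpy(), "D7", "D0")
modes = sf.assign_response_modes(rl)
gmp = ds.cell_meta["population"].to_numpy() == "GMP"
print("GMP mean likelihood (D7 vs D0): %.3f" % rl.values[gmp].mean())
print("GMP up fraction: %.2f" % (modes.mode[gmp] == "up").mean())

regs = sf.infer_modules(ds, truth.tfs, min_importance=0.1)
act = sf.aucell_scores(ds, regs, top_frac=0.05)
rss = sf.regulon_specificity(act, ds.cell_meta["population"].to_numpy())
print("top GMP regulons:", sf.select_markers(rss, n_top=3)["GMP"])

grn = sf.fit_linear_grn(ds, regs)
drv = truth.driver_map["GM"][0]
ff = sf.perturb_and_score(ds, grn, sf.PerturbationSpec.knockin(drv, ds), graph)
print("KI of %s, PS per lineage:" % drv,
      {k: round(v, 4) for k, v in ff.ps_per_lineage.items()})
```

prints

```
GMP mean likelihood (D7 vs D0): 0.676
GMP up fraction: 0.99
top GMP regulons: ['Tf03', 'Tf02', 'Tf01']
KI of Tf02, PS per lineage: {'LY': -0.0042, 'ME': -0.0039, 'GM': 0.0046}
```

The simulator's abundance design expands the GMP population progressively
after exposure, and the diffusion estimator sees it: mean `ℓ = 0.676 >
0.55`, so 99% of GMP cells are called "up" at D7. The granulocyte–
macrophage (GM) driver TF planted in the ground truth (`Tf02`) is
recovered among the top GMP marker regulons, and its in-silico knock-in
yields a positive perturbation score on the GM lineage and negative
scores elsewhere — forcing the driver up pushes cells along its own
lineage's differentiation direction.

The same workflow is available from the shell:

```bash
scregflow simulate --out fixture/ --seed 0
scregflow qc --input fixture/ --out qc/ --min-genes 10
scregflow run-all --config config.yaml --out results/ --seed 0
```

## Layout

| module | contents |
| --- | --- |
| `scregflow.synthetic` | seeded simulator: GRN, branching lineages, abundance design, QC-violation injection, fixture writer |
| `scregflow.preprocessing` | cell QC filters, log-normalization, z-scoring |
| `scregflow.abundance` | kNN graph, diffusion relative likelihood, response modes |
| `scregflow.regulons` | module inference, AUCell, RSS, markers, GMM edge filter, export |
| `scregflow.dynamics` | pseudotime normalization, adaptive sliding windows, lineage TF selection |
| `scregflow.enrichment` | single-sample gene-set scores, preranked GSEA |
| `scregflow.perturbation` | linear GRN, KI/KO propagation, flow projection, perturbation scores |
| `scregflow.config` / `scregflow.cli` / `scregflow.io` | configuration, orchestration, readers, CLI |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
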