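# hsetools

Analysis toolkit for engineered human skin equivalents (HSEs) — tissues
reconstructed from keratinocytes, fibroblasts, and vascular endothelial
cells — and for the single-cell, imaging, and biomechanical measurements
used to characterize them. The package reimplements, as a tested and
reusable library, three analysis tracks:

1. **Trajectory-constrained gene dynamics** (single-cell RNA-seq).
   Starting from a log-normalized expression matrix, a 2D embedding, a
   principal graph, and per-cell pseudotime, the pipeline extracts a
   node-to-node differentiation path (e.g. fibroblast → pericyte),
   selects the cells within the 20th percentile of cell-to-path
   distance, and scores every gene by how much of its expression spread
   a LOESS fit along pseudotime captures:

   *Dynamics Range* = (max ŷ − min ŷ) / (max y − min y)

   where *y* is observed log-normalized expression and *ŷ* the
   LOESS-fitted values (tricube weights, span 0.3, degree 2). Genes
   scoring below 0.05 (pericyte branch; 0.1 for the fibroblast branch)
   are "static" and excluded; the remaining dynamic genes are ranked by
   Spearman correlation ρ with pseudotime (Bonferroni-corrected), with
   the |ρ| > 0.7 set and the top-20 genes per direction reported as
   candidate fate-determining genes.
2. **Fiber/vessel alignment** from grayscale images: 2D-FFT magnitude
   spectrum, radial summation over angle bins in a radius annulus, and
   an alignment index (max − median)/median of the normalized angular
   profile. Reported angles are fiber axes (the 90° spectrum/fiber
   rotation is applied).
3. **Suction viscoelasticity**: from a displacement curve with
   suction/release/end phase marks, the amplitudes Uf (final
   distension), Ur (immediate retraction), Ua (total recovery), and the
   ratios R2 = Ua/Uf and R7 = Ur/Uf.

Single-cell QC (feature-count bounds, mitochondrial-fraction cutoff)
and total-count log-normalization are included, as are synthetic-data
generators that produce every input with known ground truth — so the
whole pipeline is testable without any external dataset.

## Worked example

```python
import hsetools as h

ds = h.generate_trajectory_dataset(h.TrajectorySimConfig(seed=1))
sel = h.select_cells_near_path(ds.embedding, ds.path, percentile=0.20)
res = h.run_dynamics_pipeline(ds.adata, sel, ds.pseudotime,
                              h.DynamicsConfig.pericyte_branch())
print(len(sel.cell_ids), res.top_up["rho"].iloc[0])
```

prints `100` selected cells (20% of 500) and a leading upregulated
fate gene with ρ ≈ 0.725: of the 50 genes simulated with truly
pseudotime-dependent expression, every monotone one is classified
dynamic with the correct correlation sign, and no noise-only gene
reaches the |ρ| > 0.7 fate set. The other capabilities follow the same
pattern — see `examples/`:

- `examples/trajectory_fate_genes.py` — the run above, end to end.
- `examples/qc_normalize.py` — QC report and log-normalization.
- `examples/fiber_alignment.py` — stripes at 30° recovered at 30° with
  alignment index 225.6 (coherent) vs 0.16 (pure noise).
- `examples/cutometer_ratios.py` — a curve built with elastic fraction
  0.5 and recovery fraction 0.8 returns R7 = 0.500, R2 = 0.800.

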