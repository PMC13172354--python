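# Methods

## Scope and data model

The package analyzes three kinds of measurements made on engineered
skin tissues: single-cell expression along a differentiation
trajectory, fiber/vessel orientation in micrographs, and suction
viscoelasticity curves. Expression matrices are `AnnData` objects
(cells × genes) with a `layer_tag` in `.uns` distinguishing raw counts
from log-normalized values. The principal graph and pseudotime are
*inputs*: the package does not learn trajectories or infer pseudotime,
it consumes the skeleton a trajectory tool produced.

## QC and normalization

Cells are filtered on (a) detected features (genes with count > 0) and
(b) mitochondrial count fraction (genes matching a configurable prefix,
default `MT-`). The cultured-tissue preset keeps 1000–8000 features
inclusive with mito fraction strictly below 7%; the biopsy preset keeps
cells with fewer than 7500 features (strict) and mito below 5%. The
range bounds are read literally: "1000 to 8000" is inclusive at both
ends, "less than" and "fewer than" are strict. When no gene matches the
mitochondrial prefix a warning is issued and the fraction is treated
as 0.

Normalization is `ln(1 + c·s/T)` per cell, with `c` the count, `T` the
cell total, and `s` a scale (default 10⁴, the conventional counts-per-
ten-thousand). The natural log is used; both the base and scale are
configurable. A zero-total cell raises an error naming the cell rather
than silently producing zeros.

## Path extraction and cell selection

The trajectory axis is the minimum-Euclidean-length node path between
two user-chosen nodes, computed by Dijkstra on edge lengths. Ties are
resolved deterministically to the lexicographically smallest node
sequence (greedy reconstruction over neighbours that remain on an
optimal route, tolerance 1e-9 relative).

Cell-to-path distance is the distance to the *polyline* (closed
segments, projections clamped to endpoints), not to the node set:
"distance to the path" reads as path geometry, and node-only distance
over-penalizes cells between widely spaced nodes. The selection
threshold is the q-th quantile (default q = 0.20) of **all** cells'
distances under the linear-interpolation convention between order
statistics (the common default of scientific stacks; `lower`/`higher`/
`nearest` are available for sensitivity analysis). Selection is
inclusive (distance ≤ threshold) so the degenerate all-on-path case is
nonempty.

## Gene dynamics

1. **Prefilter.** A gene is kept when its detection rate (fraction of
   selected cells with expression strictly above 0) is ≥ 10%
   (boundary inclusive: "at least").
2. **LOESS.** Expression is smoothed against pseudotime with
   single-pass tricube-weighted local polynomial regression, span 0.3
   and degree 2 by default (degree 1 available). The neighbourhood is
   the ⌈span·n⌉ nearest points; weights are `(1−(d/h)³)³` with `h` the
   neighbourhood radius; each local fit is solved by pseudoinverse so
   rank-deficient windows (e.g. heavy pseudotime ties) degrade to the
   minimum-norm fit instead of failing. Because the fitted values are
   linear in the response, the smoother is precomputed once as an
   (n × n) matrix and applied to all genes sharing the pseudotime
   vector; this makes the 500-gene pipeline run in well under a second.
   No robustness iterations are performed. All-tied pseudotime is an
   error; fewer than max(10, degree + 2) points is an error.
3. **Dynamics range.** `(max ŷ − min ŷ)/(max y − min y)`. LOESS can
   overshoot the observed extrema, so values slightly above 1 are
   possible; they are reported as computed, not clipped. A flat
   observed vector (max y = min y) is a distinct `degenerate` class —
   such genes cannot normally pass the prefilter, but robustness
   requires defined behaviour.
4. **Classification.** Scores strictly below the cutoff are `static`
   (0.05 for the pericyte-branch preset, 0.1 for the fibroblast
   branch); the score exactly at the cutoff is `dynamic`. Under the
   reference noise conditions (below) the 0.05 cutoff is permissive —
   noise-only genes often score above it — which is intentional: the
   cutoff's job is to discard near-constant genes cheaply, while the
   correlation stage does the discriminating.
5. **Spearman ranking.** Dynamic-class genes are correlated with
   pseudotime (mid-rank Spearman; p from the large-sample t
   approximation; an all-tied response is defined as ρ = 0, p = 1).
   Bonferroni correction is applied over the family of dynamic genes
   actually tested, since static genes are excluded *before* testing;
   `rho_on_all=True` instead tests every prefiltered non-degenerate
   gene, for the alternative reading in which the high-|ρ| set is drawn
   before static exclusion. The fate-gene set is |ρ| strictly > 0.7;
   per-direction top-k lists (k = 20) are ranked by |ρ| descending with
   ties broken by smaller p, then gene id — a deterministic order the
   procedure itself does not otherwise fix.

## Fiber alignment

The image mean is subtracted (removing the DC term), the array is
zero-padded to a square power-of-two side (padding preserves all
content; no windowing is applied), and the centered 2D FFT magnitude is
summed over angle bins (default 180 one-degree bins, folded mod 180°
because the spectrum of a real image is point-symmetric) within a
radius annulus (default r_min = 3 px to exclude residual DC leakage,
r_max = 45% of the side). Spectral energy of an oriented texture lies
perpendicular to the fibers, so bin angles are rotated by 90° and
**reported angles are fiber axes**. Angles follow the array convention
(x along columns, y along rows, increasing downward); an on-screen
counter-clockwise rotation therefore *decreases* the reported angle.

The alignment index is `(max − median)/median` of the normalized
profile — a package-defined scalar summarizing peak prominence (the
underlying lab practice interprets the peak shape qualitatively). A
perfectly flat profile gives 0; a profile with all energy in one bin
and zero median gives `inf`. The empirical null for 256² isotropic
noise is ≈ 0.22 (max 0.355 over 100 seeds); values above ~0.5 indicate
genuine anisotropy at this image size.

## Viscoelasticity

From a displacement curve with phase marks (suction start, release,
end): `Uf` is the maximum displacement during suction (with
interpolated phase-boundary values included so the maximum is exact on
coarse grids); `Ur = Uf − d(release + w)` with the immediate window
`w = 0.1 s` by default, because suction devices do not publish their
internal definition of "immediate"; `Ua = Uf − d(end)`. `R2 = Ua/Uf`,
`R7 = Ur/Uf`. A flat curve yields NaN ratios flagged degenerate rather
than an error. For multi-cycle recordings, apply the function per cycle
and average.

## Synthetic data

The generators define the package's reference study conditions and are
first-class, tested code.

**Trajectory datasets** (defaults: 500 cells × 500 genes, 10% dynamic,
amplitude 2, noise sd 0.3, dropout 20%): the principal graph is a
20-node polyline along a gentle sine arc (an optional side branch can
be attached; downstream analysis consumes one extracted path either
way). Cells sit at uniform arc-length positions; pseudotime *is* the
arc-length position, hence monotone along the path by construction.
Embedding points add isotropic Gaussian jitter (sd 0.3) with radius
capped at 3 sd, so every cell is provably within a known distance of
the generating polyline. Dynamic means are logistic in normalized
arc length (scale 0.12) for the monotone profiles — smooth,
LOESS-recoverable, and strictly monotone so noise-free Spearman is
exactly ±1 — and a Gaussian bump at mid-path (sd 0.12) for the
transient profile, all over a 0.2 baseline; static genes have
per-gene constant means drawn from U(0.5, 1.5). Gaussian noise is
added and values floored at 0 (truncation, mimicking log-normalized
nonnegativity), then dropout zeroes entries independently. All
randomness flows from one `default_rng(seed)` in a documented stream
order (cell positions → jitter → gene labels → static baselines →
noise → dropout), so identical configs are bit-identical. The noise
and dropout levels are fixtures chosen to be realistic for
log-normalized droplet data, not estimates of any particular dataset.

**Fiber images**: sinusoidal stripes (default wavelength 4 px) at the
requested fiber angle, linearly blended with uniform noise by the
coherence parameter. The short wavelength places the spectral peak far
from the origin where the integer frequency lattice quantizes angle
well below the 1° bin width.

**Suction curves**: a saturating-exponential rise reaching `uf`
exactly at release; an instantaneous drop of `elastic_fraction·uf` at
release followed by a short plateau (`settle_s` = 0.15 s ≥ the default
read window) so the immediate-retraction read equals the elastic drop
exactly; then a linear decline reaching total recovery
`recovery_fraction·uf` at the end of relaxation. R7 and R2 of a
generated curve therefore equal the construction parameters, which is
what makes the closed-form tests possible. Default timing (2 s suction,
2 s relaxation, 10 ms sampling) matches common suction-elastometry
protocols.

## What the simulations do and do not show

Passing tests demonstrate that the pipeline recovers planted smooth
dynamics under Gaussian noise, truncation, and uniform dropout on a
noiseless geometric trajectory. Real droplet data differ in ways the
generator deliberately omits: no UMI-level count noise or library-size
variation (values are generated directly on the log-normalized scale),
no gene–gene correlation, no doublets or ambient RNA, uniform dropout
independent of expression level, and an embedding whose geometry is
exactly the generating graph. Sensitivity/specificity measured here
are therefore properties of the method under controlled conditions,
not performance estimates for any real tissue.

## Problem sizes

The default test and reproduction runs use 500 cells × 500 genes
(selecting 100 cells), 256² images, 16² naive-DFT cross-checks, graphs
of ≤ 10 nodes for exhaustive path enumeration, and 10⁵-sample
dense-distance oracles — sizes at which every independent oracle is
exact and the whole suite runs in seconds.
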