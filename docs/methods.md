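# Methods

## Problem and model

Chondrocytes in the growth plate differentiate along a single axis (resting
→ proliferative → pre-hypertrophic → hypertrophic) while sitting in a
roughly cylindrical piece of tissue. Given a pseudotime value per cell —
computed upstream by any trajectory method and supplied as input — the
reconstruction treats pseudotime as the cylinder's long axis and recovers a
bounded 2-D cross-section per pseudotime slice:

- cells are grouped into `n_bins` (default 50) equal-width pseudotime
  intervals over [min, max]; intervals are right-closed and the lowest is
  closed on both ends so the minimum cell is never dropped; empty bins are
  allowed and logged;
- each non-empty bin is embedded by exact t-SNE into ℝ², with gradient
  descent constrained to the disk of radius `disk_radius` (default 20);
- the disks are stacked in bin order; a cell's z is its bin's pseudotime
  midpoint (preserving the pseudotemporal metric; `z_mode="index"` gives
  integer stacking instead), its (x, y) comes unchanged from the bin's disk.

The cylinder is a visualization device, not an inferred geometry: radius
units are arbitrary embedding units with no calibration to physical tissue,
and no rotational alignment is applied between consecutive disks — the
stacking is plain ordered concatenation. An inter-bin alignment hook was
deliberately not added; nothing in the procedure defines a preferred
azimuth, and aligning disks post hoc would manufacture structure.

## Constrained t-SNE

Standard exact t-SNE: conditional Gaussian affinities with per-point
bandwidth found by binary search so that 2^H equals the perplexity;
symmetrization p_ij = (p_{j|i} + p_{i|j})/(2n); Student-t low-dimensional
kernel q_ij ∝ (1 + ‖y_i − y_j‖²)⁻¹; gradient
4·Σ_j (p_ij − q_ij)(y_i − y_j)(1 + ‖y_i − y_j‖²)⁻¹; early exaggeration ×12
for the first 250 iterations; momentum 0.5 then 0.8; adaptive gains
(+0.2 / ×0.8, floor 0.01); 1000 iterations.

The boundary condition is enforced by projection, not by a penalty: after
*every* position update, any point with ‖y‖ > R is rescaled radially onto
the circle. Rescaling by R/‖y‖ can overshoot by one ulp, so the projection
iterates (and as a last resort scales to the next float below R) until the
bound holds in exact floating-point comparison. With R = ∞ the projection
never fires and the algorithm is bit-identical to its unconstrained self —
this self-equivalence, plus a central-finite-difference check of the
analytic gradient (1e-5 relative), are the correctness oracles in the test
suite. Embeddings are *not* recentered after updates: recentering could push
projected points back outside the disk.

Per-bin defaults: perplexity 30 auto-capped at ⌊(n−1)/3⌋, learning rate
max(n/12, 50), PCA initialization rescaled so the largest initial radius is
R/4 (random init: Gaussian σ = 1e-4) — both strictly feasible starts. Each
bin recomputes its own PCA (min(30, n−1) components of scaled, ±10-clipped
normalized HVG expression) and uses seed `base_seed + bin_index`; within a
bin, cells are processed in sorted-cell-id order, so results are invariant
to input row order. Bins with fewer than 4 cells (or where the capped
perplexity drops below 2) take a degenerate path: cells placed uniformly at
random within radius R/10 using the bin seed — the cylinder stays complete
without pretending t-SNE structure exists for 3 cells. The per-iteration KL
trace is recorded against the unexaggerated affinities, so the final KL is
directly comparable with the KL at the end of early exaggeration (final ≤
post-exaggeration is asserted per bin in the tests).

## Preprocessing

QC metrics per cell: total counts (library size), detected genes,
mitochondrial fraction (genes matched by a configurable prefix, `mt-` by
default — the prefix is dataset-dependent and therefore a parameter, not a
constant). Outliers at `n_mads` = 3 median absolute deviations (scaled by
1.4826 for normal consistency): library size and detected genes two-sided on
a log1p scale (count metrics are right-skewed; the raw scale is available
via `qc_log_scale=False` since the original scale choice is a convention,
not a law), mitochondrial fraction one-sided above the median on the raw
scale — a low mitochondrial fraction is not a defect. When the MAD is zero,
only cells actually differing from the median are flagged.

Gene filtering removes genes with mean raw count per cell below 1e-3 — the
only reading of a "low abundance" threshold that is unit-free at the
raw-count stage. Normalization is v = ln(1 + s·x/library) with s = 1e4;
Σ_g expm1(v_g) = s holds per cell by construction and is asserted to 1e-6
relative tolerance.

HVG ranking ("vst"): per-gene mean and variance of raw counts (ddof 1); a
local linear regression (lowess, span 0.3, no robustness iterations) of
log10 variance on log10 mean over genes with positive mean and variance
gives each gene's expected standard deviation; counts standardized with it
are clipped above at √n_cells, and genes are ranked by Σz²/(n−1) of the
clipped values. The sum is computed in closed form with an explicit
correction for the rare entries above the clip (zeros standardize negative
and never clip). Constant genes get standardized variance 0. Ties break
lexicographically on gene id for determinism. PCA centers and unit-scales
each gene, clips at ±10, and fixes signs so each component's
largest-magnitude loading is positive — repeated runs are bit-identical.

## Accessibility maps

Both fields live on one axis-aligned grid (default 40 × 40 over the
embedding bounding box with a 5% margin). The pseudotime gradient field
smooths pseudotime onto the grid with a Gaussian kernel (bandwidth 1.5 ×
mean node spacing) and differentiates numerically (central differences
inside, one-sided at the boundary). The perturbation field is the
kernel-weighted mean of user-supplied per-cell 2-vectors; how those vectors
were produced (a regulatory-network engine, a simulation, anything) is
outside this module's contract. Nodes with kernel-weighted support below
1.0 are masked and carry zero vectors. The map is the nodewise inner
product; sign classifies accessible (> 0) / inaccessible (< 0), with an
optional neutral band |ip| ≤ ε (ε = 0 by default). Grid resolution, kernel
and masking are exposed as configuration — they are display-scale choices,
not method constants. The inner product is bilinear in either field and
invariant under joint rotation of coordinates and vectors; both properties
are tested.

## Synthetic growth plate

The generator emulates the minimal structure the pipeline needs to be
falsifiable: a latent axis s ~ U[0, 1]; four zones with strictly increasing
peak centers (0.125, 0.375, 0.625, 0.875) and Gaussian bump width 0.1;
25 marker genes per zone with negative-binomial mean
μ_g(s) = base·(0.1 + A·exp(−(s − c_g)²/2w_g²)) (base 3, amplitude 3);
background genes flat along s with per-gene lognormal baseline abundances
(σ = 1, median 0.3) so the mean–variance trend has a continuum of means to
anchor on; 13 flat mitochondrial genes (mean 6, ≈5% of a healthy cell's
counts); negative-binomial dispersion 0.2 and lognormal library factors
(σ = 0.35) — a standard scRNA-seq noise model sized to make QC and HVG
selection non-trivial but solvable. Exactly round(5% · n) cells are
corrupted: library factor ×0.05 and mitochondrial counts inflated to ≈60%
of the cell total, emulating dying cells. Pseudotime is s plus Gaussian
jitter (σ = 0.02, clipped at 0), standing in for an inferred ordering
without putting a trajectory engine in the test loop. Everything is
reproducible from one seed.

What the generator does **not** emulate: batch effects, multiple lineages or
branching trajectories, doublets, ambient RNA, gene–gene correlation beyond
the shared latent axis, or realistic transcriptome-scale sparsity patterns.
Tests passing on this fixture show the algorithmic chain is correct and
self-consistent — not that any particular biological dataset will yield a
clean cylinder.

The perturbation fixture assigns each cell the local pseudotime-gradient
direction (unit vectors, interpolated from the grid field) and reverses it
inside one target zone, creating a region whose ground-truth class is known;
the accessibility test requires ≥ 90% of supported nodes inside that
region to classify inaccessible and ≥ 90% outside to classify accessible,
with node zone membership defined by kernel-weighted majority — the same
smoothing the fields themselves use.

## Numerical and design notes

- Floating-point table output uses 9 significant digits; a written table
  re-read and re-written is bit-stable (quantization happens once).
- Duplicate gene ids collapse to the first occurrence at read time (logged);
  summing duplicates would silently change library sizes.
- Orientation of count input is normalized to genes × cells, detected from
  the id-file lengths for Matrix Market input.
- The pipeline order is fixed: QC metrics → cell flags → gene abundance
  filter → normalization → HVG → binning → embedding → stacking.
- Default problem sizes (2000 cells × 5000 genes, 50 bins, 1000 t-SNE
  iterations per bin) run the full pipeline in well under a minute on one
  CPU; the exact O(n²) t-SNE is the right regime for bins of tens to a few
  hundred cells.
- Exit codes of the `gpr` CLI: 0 success, 2 configuration error, 3 data
  error, 4 numerical failure.

## Known limitations

- Pseudotime is an input; its quality bounds everything downstream.
- Consecutive disks share no azimuthal registration, so streaks of a gene
  across bins are not meaningful in the (x, y) angle — only radius-level
  and z-level patterns are interpretable.
- The accessibility map reflects local flow only: a region whose precursor
  state is inaccessible can itself still classify accessible if its local
  flow is unperturbed; lineage dependency is not propagated.
- The MAD filters assume a unimodal cell population per dataset; strongly
  mixed populations can inflate the MAD and hide true outliers.
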