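# Methods

This note documents the models, conventions and design choices behind
`spotsurf`, in the order data flows through the pipeline.

## Coordinate and grid conventions

Stacks are `(z, y, x)` voxel grids with per-axis physical spacing
`(dz, dy, dx)` in µm; the default acquisition geometry is 60 × 256 × 256
voxels at (0.2, 0.299, 0.299) µm, mirroring a 63× confocal z-stack
protocol (~55–60 optical sections, 0.2 µm z-step, 0.299 µm pixels).  The
centre of voxel `(i, j, k)` sits at `(i·dz, j·dy, k·dx)`, so an axis with
`n` voxels spans the continuous domain `[0, (n−1)·spacing]`; all continuous
sampling, interpolation and spot coordinates use this convention
consistently.  TIFF round-trips carry the voxel size in ImageJ-style
metadata (z-spacing plus x/y resolution tags).

## Synthetic stacks

The generator produces the study conditions under which the pipeline is
validated:

* **Neuron**: a soma sphere (default radius 4 µm, centred) plus
  `n_branches` (default 5) meandering tube branches (default length 15 µm,
  tube radius 0.4 µm) grown from the soma surface with a random-walk
  direction update; branch points are clamped one tube radius inside the
  stack, so long branches bend along the border rather than leave the
  volume (a soma that cannot fit raises instead).  Rasterization marks
  every voxel whose centre lies within the soma or within the tube radius
  of the densely resampled polyline, which guarantees a single 26-connected
  component.
* **Spot placement law**: rejection sampling of continuous positions
  outside the neuron with acceptance weight `m(d)/m(0)`, where
  `m(d) = 1 + A·1[d ≤ R]` (flat) or `1 + A·max(0, 1 − d/R)` (linear ramp)
  and `d` is the trilinearly interpolated surface distance.  `A = 0` or
  `R = 0` gives complete spatial randomness outside the neuron.  The fiber
  channel is modelled as point spots rather than curvilinear fibers because
  the enrichment statistic itself reduces fibers to spots; ground truth
  must live in the representation the statistic consumes.  Fiber
  tortuosity/length statistics are not modelled.
* **Rendering**: spots become 3D Gaussians whose FWHM equals the spot
  diameter (default 0.723 µm); the neuron channel is its binary mask at a
  set intensity.  Noise is applied as smooth background (Gaussian-filtered
  random field at a 5 µm correlation length, ±30% around the background
  level, clipped at 0), then Poisson shot noise at `photon_scale` expected
  photons per intensity unit, then Gaussian read noise, then a clip at 0.
  "SNR 5" in the tests means spot peak = 5 with read σ = 1 and mild shot
  noise (`photon_scale` 50), the regime in which detection fidelity is
  assessed.
* **Overlap pairs**: two raster-contiguous voxel blocks sized so that
  `|A∩B|/|A|` and `|A∩B|/|B|` hit the requested fractions to within one
  voxel of rounding; exactly one fraction being zero is rejected as
  infeasible.

What the generator does **not** emulate: depth-dependent attenuation,
spectral bleed-through, anisotropic PSF tails, multi-neuron scenes, or
curvilinear fiber geometry.  Passing tests therefore demonstrate that the
statistics recover known placement laws and overlap fractions under
realistic noise — not that segmentation choices are robust to every
real-tissue artifact.

## Background subtraction

`output = input − GaussianBlur(input, σ)` per channel, negatives clamped to
zero by default, with the physical filter width (default 46.2 µm, far above
the spot scale) converted as `σ_axis = width / (2·spacing_axis)`.  This is
a fixed, documented convention; the commercial tool this emulates describes
a two-Gaussian variant whose published coefficients are not internally
consistent, so the two σ multipliers (`pre_smooth_scale`,
`baseline_scale`) are exposed for users who want to mimic it, and the
downstream validation is contrast- and recovery-based rather than
value-based.  Widths below 2 voxels on any axis are refused.

## Detection

* **Surface**: Gaussian smoothing at the surface-detail scale (0.145 µm),
  absolute-intensity threshold, removal of components below
  `min_component_voxels`, then the largest 26-connected component.  This
  replaces manual surface tracing; validation only requires geometric
  fidelity to ground truth (Jaccard ≥ 0.9 on noiseless renders).
* **Spots**: scale-matched Laplacian-of-Gaussian at
  `σ = diameter/(2√3)` per axis (in voxels, so anisotropy is handled
  physically), response normalized so an isolated matched Gaussian spot of
  unit peak scores quality ≈ 1 — thresholds are therefore in intensity
  units.  Local maxima (3³ neighbourhood) above threshold are kept;
  equal-value plateau maxima collapse to the lexicographically smallest
  `(z, y, x)` index for determinism.  Sub-voxel centres come from the
  intensity centroid in a one-diameter window.  The quality threshold is a
  per-dataset choice (as it is in practice); at SNR ≈ 5 the tests use 3.2 ×
  read-noise σ, the precision/recall balance point measured on an
  independent calibration render.
* **Binarization** of fragmented fiber channels is the same smoothing +
  threshold without component selection; empty results are allowed and
  logged.

## Distance field and Monte Carlo null

Distances are **exact anisotropic Euclidean distances to the nearest
surface-voxel centre**, zero everywhere inside the mask, computed with the
separable lower-envelope (Felzenszwalb–Huttenlocher) algorithm in float64
(numba-compiled; ~0.5 s per 60 × 256 × 256 stack).  scipy's EDT serves as
an independent cross-check in the tests; a brute-force minimum over surface
voxels bounds the error at 10⁻⁶ µm.  Spot distances are trilinear
interpolations of this field, which is consistent to within one voxel
diagonal of nearest-voxel lookup and exact on voxel centres.

The null places the observed number of spots uniformly in the stack volume
**excluding the neuron interior** (the generator excludes it physically, so
the null must too; the behaviour is configurable via
`null.exclude_interior`).  Each of the default 1000 replicates is binned
identically to the observation; per-replicate unbinned counts always sum to
the spot total.  Because observed and null spots share the bounded imaging
volume, stack-border effects cancel in the normalized percentage (verified
by translating neurons to the border).

## Enrichment, testing and the radius

Normalization is **per neuron**: each neuron's observed bin counts are
divided by the mean of its own null ensemble (×100).  Bins whose null mean
is zero are undefined and excluded from testing.  Cohort inference:

* Two-way fixed-effects ANOVA (Type II) on dataset (observed vs null) ×
  distance bin with neurons as replicates reports the interaction.  The
  null arm, normalized by its own mean, is exactly 100 for every neuron;
  the per-bin observed-vs-null contrast therefore reduces algebraically to
  a one-sample t of the per-neuron percentages against 100, which is how it
  is computed.  Repeated-measures structure across bins within a neuron is
  not modelled (fixed-effects only), a deliberate simplification.
* Šidák adjustment `p_adj = 1 − (1 − p)^m` with family size m = number of
  bins tested (15 fine or 6 coarse), computed via `expm1/log1p` for
  precision at tiny p.
* **Radius rule**: the upper edge of the last bin in the maximal contiguous
  run starting at 0 µm with adjusted p < α and mean above 100.  A
  non-significant first bin gives radius 0.
* Cohort-vs-cohort comparisons use per-bin Welch t-tests with Šidák
  adjustment, reporting two-sided and both one-sided directions, plus a
  cohort × bin ANOVA and the radius ratio (defined as 1 when both radii are
  0).

Under the flat kernel the expected enrichment inside R is
`100·(1+A)/(1 + A·f)` where `f` is the volume fraction within R of the
surface — bins beyond R fall *below* 100% because the spot budget is fixed;
the radius rule only reads the enriched run, so this depletion does not
bias the estimate.

## Colocalization and volumetry

Overlap is voxel-wise intersection volume with both directional fractions;
ROI aggregation is volume-weighted pooling (`100·Σ|∩|/Σ|A|`), chosen over
the mean of per-ROI ratios so that each ROI contributes in proportion to
its volume; per-ROI mean ± SEM is reported alongside.  Soma
double-positivity uses an overlap threshold of 50% of the soma's own volume
(or centroid containment), a documented surrogate for by-eye counting.
ROI crops convert physical size to voxels by rounding
(`round(size/spacing)`), so a 5 µm slab at 0.2 µm z-spacing is exactly
25 voxels and an 18.5 µm square at 0.299 µm pixels is 62 voxels.  Marker
volume percentages are normalized to the two-marker total (summing to 100
by construction); the cohort comparison is an unpaired two-tailed pooled-t
across ROIs.

## Geometry arithmetic

Pure closed forms over literature constants (single-arbor coverage 2.7% of
the striatum, 75,000 neurons per arbor volume, 0.6% GDNF⁺ neurons, 7,600
nigral dopamine neurons, MSN/PV abundances 95%/0.7%) and measured values
(volume split 7.61%/92.39%, distance ratio 7).  Fraction-valued arguments
must lie in (0, 1]; percent-scale magnitudes passed where a fraction is
required raise, because silently mixing the two scales is the dominant
failure mode of this arithmetic.  No uncertainty propagation is attempted
(the constants carry none).

## Problem sizes and numerical choices

The cohort studies run 40 neurons on full-size default stacks with 300
spots per neuron and 1000-replicate nulls — chosen to match the cohort size
a single-lab imaging study realistically collects while keeping a full
simulation–recovery cycle at desk scale (minutes on one CPU).  Unit tests
use smaller isotropic grids where the geometry is analytically checkable.
Seeds propagate from a single top-level seed through
`numpy.random.default_rng`; equal seeds give bit-identical masks, spots,
stacks and CSV outputs.  Degenerate inputs (empty masks, full-volume
exclusions, zero-size ROIs, constant ANOVA responses, zero pooled variance)
raise typed errors or return the documented closed-form limits rather than
NaNs.

## Known limitations

* The spot model ignores fiber connectivity; analyses that depend on
  tracing (path lengths, branching) are out of scope.
* Enrichment inference treats bins as independent comparisons after Šidák;
  spatial correlation between adjacent bins is not modelled.
* The null is CSR in the imaged box; it does not model exclusion by other
  (unsegmented) structures in real tissue.
* Manual-tracing variability and chromatic registration error have no
  synthetic counterpart, so recovery results bound algorithmic — not
  operator — error.
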