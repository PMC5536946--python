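# Methods

`nanopack` quantifies how tightly membrane proteins pack into plasma-membrane
nanoclusters, using four complementary readouts — super-resolution spot
morphometry, lateral mobility (FRAP), surface/internal localization, and
antibody accessibility — plus a synthetic-data layer that generates every
input with recorded ground truth.  This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic
benchmarks do and do not establish about real data.

## Synthetic ground truth

### Clustered molecule fields

Cluster centres follow a homogeneous Poisson process over a square field;
defaults place 50–75 molecules uniformly inside disks of 50–60 nm diameter at
densities around 14–19 clusters/µm², the regime reported for syntaxin-type
nanoclusters.  An optional free-monomer pool is a second, independent Poisson
process.  `min_separation_nm` switches the centre process to hard-core
dart-throwing (the Poisson-drawn count, placed with a minimum spacing) for
benchmarks that require optically resolvable clusters; the default remains
pure Poisson.

### Antibody shielding (random sequential adsorption)

Antibody labelling is irreversible, sequential and sterically exclusive: in
random order, each epitope binds with probability `label_efficiency` unless an
already-bound epitope lies strictly within `footprint_diameter_nm` (default
12 nm, the lateral extent of an IgG; the geometry is a modelling choice — no
measured footprint exists for this system).  Because the blocked set only
grows, a single randomized pass reaches the jammed state; the
`binding_attempts` parameter is kept for interface completeness but cannot
change the outcome.  In the dense-epitope limit the model approaches the
hard-disk RSA jamming coverage (~0.547), which the tests verify by
extrapolating coverage against (candidate count)^(-1/2) — the known RSA
kinetic law — rather than by asserting the literature constant directly.
This model reproduces the central phenomenology: per-epitope occupancy is a
monotonically decreasing function of local packing density, so staining
intensity under-reports tightly packed pools.

### Image rendering

Each bound antibody is an isotropic 2D Gaussian evaluated at pixel centres
(confocal FWHM 250 nm, STED FWHM 60 nm by default, 20 nm pixels).  Kernels
are truncated at 5σ (relative mass error < 4 × 10⁻⁶).  Noise is Poisson on
expected photons, then Gaussian read noise, then a constant camera offset;
with `noise=False` rendering is exactly linear in the emitter set, which the
tests exploit.  No vectorial PSF physics, depletion-power dependence or 3D
effects are modelled: measured sizes are PSF ⊗ cluster, nothing finer.

### FRAP simulator

A mobile concentration diffuses by explicit finite differences (5-point
Laplacian, zero-flux mirror boundaries, mass conserved to < 10⁻⁶ relative)
while an immobile concentration stays fixed; both are multiplied by
(1 − `bleach_depth`) inside a centred 12 × 12 px region at the bleach event.
The integration step is 0.9× the explicit stability bound dx²/4D; a
user-supplied step above the bound is refused with the required step in the
error message.  Acquisition follows the 1 Hz protocol: 10 pre-bleach frames,
a 500 ms bleach window, 200 post-bleach frames at 414 nm/px.  The bleach
laser acts throughout its window, so the depleted state exists at the
window's end and the first post-bleach frame is recorded there; this keeps
recovery time zero aligned with the first sample, preserving the exact
t½ ∝ 1/D self-similarity of linear diffusion (verified across a 4× range of
D to within ~5%; residual deviation comes from the finite field, whose ~3%
fluorescence loss to the bleach is felt earlier at higher D).  The grid
default (96 px) is 8× the ROI width to keep boundary effects small.

### Quench pairs, slice stacks, EF/WB tables

* pH-quench: cells are uniform disks with lognormal per-cell brightness; the
  pH 4.3 image carries `1 − surface_fraction × quench_efficiency` of each
  cell's signal.  Whether brief acidic incubation partially quenches internal
  pools is unknown; `quench_efficiency` parameterizes it, default 1.
* Slice stacks: per x-z slice, an elliptical cell with a ~4 px membrane band
  (marker stain plus the membrane antibody pool) and a uniform interior pool;
  the marker bleeds into the antibody channel with coefficient 0.06.
* EF/WB: per transfection pair, EF = batch × expression × accessibility ×
  noise and WB = batch × expression × noise, with lognormal (unit-mean)
  noise of coefficient of variation `noise_cv` and lognormal batch scales —
  deliberately large, as real blot/imaging batches vary by orders of
  magnitude.

## Analysis stages

### Spot morphometry

Detection runs on the difference-of-Gaussians filtered STED image inside a
square analysis region (180 px continuous-wave mode / 130 px pulsed mode).
The maxima rule is deliberately simple and oracle-checkable: a pixel is a
spot iff its DOG value is ≥ all 8 neighbours, exceeds the prominence
threshold, and is the smallest (y, x) member of its equal-valued plateau.
DOG scales default to σ = 1 and 3 px, matched to ~60 nm spots at 20 nm/px;
they are calibration choices exposed in `SpotAnalysisParams`.  Spot intensity
is the mean over a 5-px-diameter circular ROI on the *raw* image (pixels
whose centres lie within 2.5 px); spots below the weak-spot gate (100 a.u.
CW, 4 a.u. pulsed) are discarded.  Size comes from 15 × 3 px horizontal and
vertical band profiles fitted with Gaussian + constant offset; the higher-R²
orientation is kept and FWHM = 2√(2 ln 2)·σ·pixel.  Size eligibility requires
R² ≥ 0.9 plus quantified "suitable fit" criteria: fitted peak within 2 px of
the scan centre, positive height, offset inside the image intensity range
(with a 10⁻³ dynamic-range tolerance for float round-off).  Spots too close
to the border for a full line scan stay in density/intensity statistics but
are size-ineligible.  Nearest-neighbour distances use centres of mass of raw
intensities within the circular ROIs (raw rather than filtered intensities —
the choice is not uniquely determined by precedent); a lone spot gets +∞ and
passes the NND gate (≥ 5 px CW / 6 px pulsed).  Sheet summaries average
intensity over all gated spots but size only over spots passing both the fit
and NND gates, and relate them to the background-corrected confocal mean.

### FRAP analysis

Traces are per-frame ROI means with a frame-wise background-ROI subtraction;
ROIs must be pairwise disjoint rectangles inside the frame.  Drift QC
compares the background-corrected control region's first 10 frames to its
last 3: a relative difference strictly above 15% excludes the recording
(exactly 15% is retained).  The post-bleach segment, re-zeroed at the first
post-bleach frame, is fitted with F(t) = offset + amplitude·t/(t½ + t) by
least squares; initialisation uses the first point (offset), the span
(amplitude) and the first half-span crossing (t½), with t½ bounded in
(0, 10 × duration].  R² is computed on the fitted segment only; fits below
0.7 are flagged unaccepted, flat traces return an unaccepted fit rather than
raising.  Traces are fitted in background-corrected raw units; an optional
pre-bleach normalization flag exists, and t½ and R² are invariant to any
positive rescaling.  Half-time vs expression uses the pre-bleach mean as an
expression proxy and Spearman rank correlation (omitted below 3 cells or for
degenerate constant inputs).

### Localization

The quench analysis computes per-cell background-corrected means from a
shared label mask and reports the pH 4.3 / pH 7.4 ratio; cells whose
corrected reference intensity is non-positive are skipped with a warning.
The slice-stack analysis interprets "expanded by five pixels" as symmetric
morphological erosion (inner ROI, cytosol) and dilation (outer ROI, whole
cell) of the traced membrane region with a disk structuring element — the
closest operational reading of a contour offset.  The antibody channel is
first corrected for 6% marker bleed-through (clamped at zero), a scalar
per-pixel background measured on non-transfected control cells is subtracted
via the ROI areas, and the summed cytosol/whole-cell integrals give a
fraction clamped to [0, 1].  Cell masks are explicit inputs (label TIFF or
polygon JSON), replacing manual outlining.

### Accessibility

The EF threshold replaces a manually chosen background level with the 99.9th
percentile of pooled mock-transfected images (per staining batch) — a
deterministic, auditable stand-in.  Thresholded integrals are divided by
nucleus counts from the shared maxima detector at DAPI scale, with maxima
brighter than `aggregate_threshold` rejected as staining aggregates.  EF/WB
ratios are paired within transfections; the paired t-test runs on the
non-normalized ratios, with normalized ratios reported for display as
arithmetic mean ± SEM.  Because the noise is multiplicative, the arithmetic
mean of ratio estimates is upward-biased; the summary therefore also carries
the geometric mean, which is the consistent estimator of the accessibility
ratio and the quantity used in the recovery benchmarks.  For the toxin
comparison, co-transfected cells below the single-transfection cohort's mean
GFP level are excluded, and per-condition intensities are *multiplied* by
(condition mean area / grand mean area): cells that shrink concentrate their
signal, so the raw mean intensity would over-credit them.  The inverse
reading (divide) is implemented behind `size_correction="divide"` but the
multiplicative form is the default.

## Benchmarks and their scope

The test suite regenerates every benchmark at run time: spot sizes at 80 nm
effective FWHM recovered within 10% over 20 sheets (closed-form exact to
0.1% noiseless); densities at 16 clusters/µm² within 15% over 20 seeds;
detector equivalence with brute-force enumeration on 200 random fixtures;
hyperbola recovery exact on noiseless input and within 10% at 5% noise over
100 replicates; t½ × D constant within 10% over a 4× D range; drift QC exact
at the 10/15/20% points; monotone shielding over an 8-point density sweep;
EF/WB ratio exactly 3 noiseless and recovered (geometric mean, log scale)
within 3 SE over 500 replicates of 14 pairs at cv 0.3; quench remaining
fraction 0.30 within 3 SE over 100 cells and cytosolic fraction 0.40 within
5% over 10 seeds.  Problem sizes (image sizes, replicate counts, sweep
lengths) were chosen so the whole suite runs in well under a minute-scale
budget on one core while keeping Monte-Carlo error far below each tolerance.

Passing these benchmarks shows the implementation is faithful to its own
models; it does not validate the models against real microscopes.  Real STED
data have structured background, non-Gaussian and spatially varying PSFs,
fixation artefacts and fusion of adjacent clusters into strings — none of
which the generators emulate.  Real FRAP recordings include acquisition
bleaching, membrane topography and reaction-limited binding; the simulator
is pure 2D diffusion plus an immobile pool, so fitted half-times are
apparent mobilities, not diffusion coefficients.

## Known limitations

* The hyperbola is an empirical recovery model; for pure diffusion it fits
  with R² > 0.99 but its t½ is a relative mobility index.
* The RSA footprint and label efficiency are not identifiable from a single
  staining intensity; the shielding model supports relative, not absolute,
  packing statements.
* Sub-resolution cluster pairs merge into single spots; density recovery
  assumes separations well above the PSF.
* Gel densitometry is out of scope: WB values enter as band/loading-control
  numbers from a CSV.
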