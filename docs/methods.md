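# Methods

This note documents the models, numerical choices and assumptions
behind each stage of the pipeline, the design decisions that were
genuinely open, and what the synthetic-data tests do and do not show
about real data.

## Elastic model and traction reconstruction

The substrate is treated as a semi-infinite, isotropic, linearly
elastic half-space with Young's modulus *E* (default 4500 Pa), Poisson
ratio ν (default 0.5, incompressible) and imaging scale 0.153 µm/px.
Tangential surface traction and surface displacement are related in
Fourier space by the Boussinesq kernel

G(k) = 2(1+ν)/(E·k³) · [[(1−ν)k² + ν·k_y², −ν·k_x·k_y], [−ν·k_x·k_y, (1−ν)k² + ν·k_x²]],

with angular wavenumbers in rad/µm, so G carries µm/Pa.  The forward
model multiplies the FFT of the traction grid by G; the inverse
(`fttc_reconstruct`) solves T(k) = (GᵀG + λI)⁻¹Gᵀu(k) per wavevector
(0th-order Tikhonov).  Both set the k = 0 term to zero: for a balanced
load the mean displacement of a half-space is undetermined, and an
equilibrated cell exerts no net force.

Numerical choices:

- **Grid.** Reconstruction runs on the PIV node grid (16 px = 2.448 µm
  spacing), not an interpolated pixel grid: the measurement resolution
  is set by PIV, and interpolation would manufacture data.
- **Padding.** Fields are mean-subtracted and zero-padded to the next
  power of two (at least `pad_factor`× the grid, default 2) before the
  FFT; the result is cropped back and re-zero-meaned so the returned
  field balances at machine precision.  Because the half-space
  response is long-ranged, the accuracy of both directions depends on
  how far the displacement has decayed at the crop boundary; the
  default synthetic scene keeps a wide cell-free margin for exactly
  this reason.  No taper window is applied by default.
- **Regularization.** λ defaults to 1e−10 and adds to GᵀG in (µm/Pa)²
  units, where kernel entries at the grid scales used here are
  ~1e−4…1e−2 µm/Pa; λ therefore acts as a numerical stabilizer rather
  than a smoother, and the reconstruction fidelity rests on the
  quality of the PIV field.  λ's effective strength depends on the
  units convention for G — conventions differ between published FTTC
  codes and the right value is not transferable between them — so λ
  is exposed as a parameter everywhere.
- **Verification.** The Fourier forward model is checked against an
  independent real-space convolution of the Boussinesq kernel
  u_i(r) = (1+ν)/(πE)·[(1−ν)δ_ij/r + ν·x_i·x_j/r³]·F_j with
  subdivided near-field quadrature and the analytic self-cell integral
  (∫dA/r over a square = 4h·asinh 1); agreement is better than 1%
  interior relative L2 on a 64×64 grid.  The forward→inverse round
  trip on a noiseless planted dipole recovers the interior field to
  0.3% relative L2 and the peak to 0.01%.

## Drift correction and PIV

Stage drift is estimated by normalized cross-correlation template
matching with sub-pixel refinement and removed by spline translation.
The default template is the central frame region excluding a 1/8
margin per side: a large template stays anchored on the static
majority of the bead carpet even where the cell deforms the gel
locally, which keeps the correlation peak above the 0.5 alignability
floor; small central templates fail exactly over the cell.

Displacements are measured by window cross-correlation on a
coarse-to-fine schedule (64 px, then 32 px windows at 50% overlap,
yielding one vector per 16 px).  The validated coarse field acts as an
integer predictor offset for the fine pass, extending range beyond the
quarter-window rule (a 20 px shift is recovered exactly).  Details
that matter for accuracy:

- **Apodization.** Interrogation windows are Hann-tapered.
  Rectangular windows suffer two coupled artefacts: the triangular
  overlap envelope of linear correlation biases sub-pixel peaks toward
  zero lag, and beads truncated at the window edge contribute broadband
  noise (0.1–0.2 px rms at ~25 beads/window).  With the Hann taper and
  its autocorrelation envelope divided out around the peak, planted
  uniform shifts are recovered with ≤0.07 px worst-vector error.
- **Sub-pixel peak.** A 2-D Gaussian is fitted through the 3×3 peak
  neighbourhood (least-squares quadratic in log space).  Per-axis
  3-point fits leak displacement between axes whenever the correlation
  peak is tilted — on random bead patterns this alone contributes
  ~0.05 px rms to the axis perpendicular to the motion — and remain
  only as the fallback for non-positive neighbourhoods.
- **Validation.** The normalized median test (Westerweel–Scarano
  form) uses the 30 nearest valid neighbours by grid distance, noise
  level ε = 0.2 px and threshold 5.0; residuals are computed per
  component in px, decisions are taken simultaneously from the input
  field, and rejected or invalid nodes are replaced by the
  neighbourhood median.  On planted 5% gross outliers the test reaches
  100% sensitivity at 0% false replacements; it is idempotent on
  smooth fields.  Validation runs after every pass (per-pass ordering
  is an assumption; the alternative, final-only, is configurable by
  disabling `validate_each_pass`).

## Force profiling

Cell masks come from Otsu thresholding + closing + largest component +
hole filling.  Force foci are connected components of traction
magnitude above the noise floor; a component carrying several strong
local maxima (≥3× floor, ≥8 µm apart) is split between them by
marker-based watershed.  The split matters in practice: adjacent foci
are frequently joined by one-node-wide bridges of reconstruction
noise, and plain connected components under-count them.  Components
smaller than 50 µm² (about half the area of an 8 µm focus) are
dropped as speckle.

The noise floor is the 95th percentile of traction magnitude over a
cell-free region — with default imaging parameters it lands at
~45–55 Pa, matching the ~50 Pa level typical of this gel/imaging
configuration, so a 50 Pa "above-noise" threshold transfers.

Per-cell force profiles collect traction-magnitude percentiles
(deciles plus 95th and 99th — the exact percentile grid is an
assumption and configurable), mean, max, median, standard error
(sd/√n over grid nodes in the mask) and the area above the noise
floor; with normalization enabled every feature is divided by the
cell area in µm² (the literal reading of area normalization; a
densities-only alternative is available by disabling the toggle).
Traction values are sampled at grid nodes whose nearest pixel lies in
the mask, keeping profiling at measured resolution.  The periphery
partition takes all mask pixels within 2 µm (default) of the edge by
Euclidean distance transform; periphery and interior are pixel-exact
complements within the mask.

## Subpopulation discovery

Profiles are z-scored per feature (n−1 convention; constant features
are an error naming them).  PCA is exact SVD with a deterministic sign
convention (largest-|loading| positive).  The number of informative
components is chosen by permutation parallel analysis: each feature
column is permuted independently, the explained-variance spectrum
recomputed (default 100 permutations), and PCs count as significant
from PC1 until one fails to exceed the 95th null percentile of its own
rank.  On null data the procedure returns 0 components at
approximately its nominal level; on planted two-factor data it
returns 2.

Two clustering routes operate on the significant-PC scores:

- **PAM** (k-medoids, classical BUILD + best-improvement SWAP,
  implemented here; deterministic with index tie-breaks) at a
  user-chosen k (default 3).  k is a required parameter; no selection
  heuristic is implied.
- **kNN → SNN → Louvain**: Euclidean kNN lists (ties broken by cell
  index), Jaccard overlap of neighbourhoods (self included) as
  undirected edge weights with non-positive edges pruned, Louvain
  modularity communities at resolution 1.0 (seeded).  The default
  neighbourhood size is k = 20 capped at n−1, the convention of
  single-cell graph clustering: at n = 60 smaller choices such as
  k = √n fragment 20-cell groups (ARI drops to ~0.7), while any
  k ≥ 12 recovers planted partitions perfectly.

The PC1 trajectory orders cells along the first component and reports
the Spearman correlation between PC1 score and mean traction — on
contractility-dominated cohorts |ρ| ≥ 0.9, connecting the discrete
clusters to a continuous low-to-high force axis.

## Orientation and AFM

F-actin orientation uses the structure tensor: Gaussian-derivative
gradients (σ = 1 px), tensor components smoothed in a Gaussian
analysis window (default σ = 4 px), fibre angle from the minor
eigenvector mod 180° (counterclockwise from the image x-axis with y
up), coherence (λ₁−λ₂)/(λ₁+λ₂) ∈ [0,1], zero where the tensor
vanishes.  Striped fixtures at known angles are recovered to <0.1°;
white noise gives coherence <0.2.  Per-cell cytoskeletal features:
area and aspect ratio from the mask; stress-fibre length as the mean
geodesic length of skeletonized super-threshold ridges (edge-weighted:
1 or √2 px per step — a stand-in definition, since fibre-length
measurement conventions vary); orientation dispersion as the
coherence-weighted circular standard deviation of the doubled angles.

Hertz fits minimize squared residuals of F = A·max(z−z₀, 0)^{3/2}
jointly over log E and the contact point z₀ (bounded least squares,
baseline-threshold initialization).  Joint contact-point fitting was
chosen over threshold detection because it is unbiased on noisy
curves; results flagged non-converged when the solver fails or E pins
at a bound.  The sample Poisson ratio defaults to 0.5 (incompressible
tissue) as an assumption.  Noiseless synthetic curves recover E to
<0.01%; 5% force noise keeps recovery within 5%.  `stiffness_map`
fits a grid of curves (e.g. 10×10), tolerating missing or failed
curves as NaN, and reports median and MAD.

## Synthetic data: what it does and does not emulate

The scene generator plants Gaussian traction foci in antiparallel
dipole pairs — cells are force dipoles, and FTTC assumes zero net
force — and removes the residual discretization imbalance with a
broad, weak counter-traction (<1 Pa in the default scene).  Beads are
uniform random points rendered as Gaussian PSF spots (σ = 1.5 px ≈
0.23 µm, diffraction-limited scale) with ±30% brightness variation,
displaced bilinearly by the forward-model field, shifted by stage
drift, and degraded with additive Gaussian noise.  Bead density and
PSF width are assumptions (no standard values exist); the defaults —
1 bead/µm², ~24 beads per fine window — are typical of dense TFM
seeding.  The default photon noise (sd 0.10 of unit bead amplitude)
is calibrated so the reconstructed cell-free noise floor sits at the
~50 Pa design point.

Default study scene: a 1024×1024 px (157 µm) field with four foci of
600–800 Pa peak and σ = 4 µm at ≥30 µm (≥6σ) pairwise separation,
within a central cell footprint.  Separations this large are needed
because window-PIV leaks a few percent of a focus' stress into its
surroundings, and the leakage — not the optics — limits how close two
foci can sit and still segment apart at a ~50 Pa threshold.

Not emulated: optical physics beyond a Gaussian PSF, finite gel
thickness, 3-D deformation, bead detachment, temporal image series
beyond one pair, and spatially correlated camera noise.  Passing the
planted-recovery tests therefore demonstrates the correctness of the
measurement chain under its own model assumptions, not robustness to
every optical artefact of real microscopes.

Cohorts for clustering are drawn feature-wise from per-group
Gaussians.  The default (n = 60, three groups of 20, neighbouring
group means 4 within-group sds apart on the signal features, the
intermediate group elevated on half of them so the groups span two
dimensions, plus 4 pure-noise features) emulates a ~60-cell cohort
with low / intermediate / high contractility subpopulations.

## Problem sizes

Tests and the acceptance script use: one 1024² px scene (~25k beads,
63×63 final PIV grid) for the image-level chain; 64×64 grids for the
forward/inverse oracle; 256² px bead patterns (1500 beads) for PIV
accuracy; 10 seeded 60-cell cohorts for clustering; 20 seeded curves
for noisy Hertz recovery.  These sizes were chosen so the full suite
completes in a few minutes while keeping every estimate comfortably
inside its tolerance.

## Known limitations

- The reconstruction inherits periodic-boundary truncation error from
  the finite field of view; fields whose displacement has not decayed
  at the crop boundary acquire a ~20 Pa artefact floor.
- λ = 1e−10 is not transferable across G-unit conventions (see above).
- PAM is O(n²k) per SWAP sweep — fine for cohorts of tens to hundreds
  of cells, not for thousands.
- The CLI's simulate/tfm/profile stages operate on the synthetic
  scene layout; applying the pipeline to real microscope data means
  calling the library functions on your own TIFFs and masks.
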