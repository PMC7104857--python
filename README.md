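# celltraction

Single-cell traction force microscopy (TFM) analysis for contractile
cells — myofibroblasts and other stromal cells — cultured on soft
elastic hydrogels, together with the auxiliary quantifications that
round out a biophysical cell profile: structure-tensor F-actin
orientation analysis and Hertz-model AFM nano-indentation fitting.

The package takes a pair of fluorescent fiducial-bead images (a
relaxed, cell-free reference and a stressed, cell-attached frame) and
turns them into:

1. a drift-corrected, validated **displacement field** (iterative
   cross-correlation PIV, 64→32 px windows, normalized median test);
2. a regularized **traction stress map** (Fourier-transform traction
   cytometry, FTTC);
3. per-cell readouts: segmented **force foci**, periphery/interior
   force partitions, and meta-signature **force profiles** (traction
   percentiles + summary statistics, normalized to cell area);
4. unsupervised **biophysical subpopulations** from cohorts of force
   profiles: PCA with permutation-based component selection, PAM
   (k-medoids) clustering, and kNN → shared-nearest-neighbour →
   Louvain graph clustering, with a PC1 contractility ordering.

A synthetic-data module generates every input with known ground truth
— planted traction foci pushed through the elastic forward model and
rendered into bead images — so the whole pipeline is verifiable end to
end without any external data.

## The model

The gel is an isotropic, linearly elastic half-space (Young's modulus
*E*, Poisson ratio ν).  A tangential traction field **T**(x) on its
surface produces the surface displacement **u**(x) through the
Boussinesq solution; in Fourier space

```
u(k) = G(k) · T(k),
G(k) = 2(1+ν) / (E k³) · [ (1−ν)k² + ν k_y²     −ν k_x k_y
                            −ν k_x k_y           (1−ν)k² + ν k_x² ]
```

with k = |**k**|.  PIV measures **u** on a regular grid; FTTC inverts
the relation per wavevector with 0th-order Tikhonov damping,
T(k) = (GᵀG + λI)⁻¹ Gᵀ u(k), λ = 1e−10 by default, and the k = 0 term
set to zero (a cell in mechanical equilibrium exerts no net force).
Defaults follow a standard soft-gel TFM configuration: E = 4.5 kPa,
ν = 0.5, pixel size 0.153 µm, final PIV vector spacing 16 px = 2.4 µm.

For the AFM module, the force on a spherical tip of radius R indenting
an elastic sample to depth δ follows the Hertz law
F = (4/3)·E/(1−ν²)·√R·δ^{3/2}; the fitter estimates E and the contact
point jointly, and cantilever spring constants come from thermal
(equipartition) calibration, k = k_B T/⟨x²⟩.

## Worked example

The `celltraction` command chains the stages on a synthetic scene —
four planted force foci (600–800 Pa, σ = 4 µm, arranged as two
contractile dipoles) on a 4.5 kPa gel, imaged as ~25k beads across a
157×157 µm field with stage drift and photon noise:

```
$ celltraction all --seed 9 --outdir run
scene written to run (4 foci, 24546 beads)
traction written; net force (1.79e-11, -2.73e-12)
4 foci above 52.3 Pa
```

Reading the output: the scene generator plants 4 foci and renders the
bead pair plus a cell-channel image; the `tfm` stage drift-corrects,
runs PIV and reconstructs traction whose components sum to zero (the
force-balance contract, here at 1e-11 nN); the `profile` stage
estimates the cell-free noise floor (52.3 Pa — by design close to the
~50 Pa floor typical of this imaging configuration), segments the
traction map above it, and recovers exactly the 4 planted foci.
`run/force_foci.csv` lists each focus with its area (~400 µm²),
equivalent diameter, mean and peak stress (~820–900 Pa against
600–800 Pa planted peaks), centroid and eccentricity;
`run/traction_heatmap.png` shows the reconstructed stress map.

The same stages are available as library functions:

```python
import numpy as np
from celltraction import (default_scene, plant_traction_field,
                          forward_displacement, render_bead_images,
                          drift_correct, iterative_piv, fttc_reconstruct)

scene = default_scene(seed=9)
truth = plant_traction_field(scene)            # ground-truth Pa field
disp  = forward_displacement(truth)            # Boussinesq forward model
ref, deformed, beads = render_bead_images(scene, disp)
stack, drift = drift_correct(np.stack([ref, deformed]))
field = iterative_piv(stack[0], stack[1], scene.substrate.pixel_size)
traction = fttc_reconstruct(field, scene.substrate, lambda_reg=1e-10)
```

Cohort-level clustering runs on any cell-by-feature CSV
(`celltraction cluster --profiles profiles.csv`), so cytoskeletal
morphology features (cell area, aspect ratio, stress-fibre length,
orientation dispersion from `extract_cytoskeletal_features`) go
through the same PCA → PAM / SNN-Louvain path as force profiles.

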