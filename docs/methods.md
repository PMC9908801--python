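# Methods

`spect-bench` is a self-contained benchmark for post-reconstruction deep-learning
denoising of gated myocardial-perfusion SPECT (MPS).  It reproduces the full
comparison workflow — gated acquisition, reduced-time resampling, OSEM
reconstruction, patch-based denoising with four 3D network architectures,
artificial perfusion-defect insertion, and task-based evaluation — on synthetic
data generated by its own digital phantom, so every number the package reports
is computable from a seed.

## System model

The projector is an attenuated parallel-beam model with a depth-dependent
collimator response, built as rotate-volume-then-sum:

1. **Rotation.**  For each view the in-plane rotation is realised as a cached
   `scipy.sparse` matrix that *splats* each voxel (as a 2x2 sub-pixel lattice)
   onto the rotated grid with bilinear weights.  Splatting conserves counts
   exactly for content inside the field of view; sub-pixel splitting suppresses
   the lattice-aliasing modulation of a plain splat to <1 % on smooth images.
   Angles that are multiples of 90 degrees use exact index permutations.
   Because the rotation is an explicit matrix, the back projector is its exact
   transpose and the adjoint identity `<Ax, y> = <x, A'y>` holds to float
   round-off — the property the multiplicative EM update relies on.
2. **Attenuation.**  Voxel-centred cumulative sums of the rotated attenuation
   map along the projection axis, with half-voxel self-attenuation for the
   emitting voxel (`mu` in 1/cm at 140 keV; soft tissue 0.15/cm).
3. **Collimator blur.**  A separable 2D Gaussian per depth plane with
   `sigma(d) = sigma0 + slope * d` (defaults 1.5 mm + 0.02/mm, generic
   low-energy high-resolution values, configurable and disableable).  The
   kernel is symmetric with zero-padded boundaries, hence self-adjoint.

The orbit default is 64 projections over 180 degrees (half-open, no duplicated
opposite view), 4.8 mm pixels.

## Phantom and gated acquisition

One synthetic "patient" is a short-axis-aligned left-ventricle half-ellipsoid
shell (apex toward -z): the wall lies between co-centred endo/epi ellipsoids
(defaults 24/24/36 mm vs 34/34/46 mm, i.e. a 10 mm wall) cut at the equatorial
plane, with uniform myocardial uptake, 10 % background in an elliptic-cylinder
soft-tissue body, and uniform attenuation inside the body.  The seed perturbs the LV by up to +/-10 % to create
inter-patient variability; the jitter scales the mid-wall surface and the wall
thickness *separately* (scaling endo and epi axes independently would produce
nonphysiologic 3 mm or 17 mm walls, which in early experiments dominated the
normal-database variability as spurious apical-thinning "patients").  The
half-shell volume is analytically `(2/3) pi (a2 b2 c2 - a1 b1 c1)`, which the
voxelization matches to ~5 %.

Gated acquisition draws `n_gates = 8` independent Poisson realisations of the
noise-free projections scaled so the grand total matches the requested count
level.  Default stress/rest totals are 4e5 / 1.2e6 counts, a 1:3 ratio
mirroring typical one-day-protocol dosing; absolute levels were fixed once to
give clinically plausible myocardial noise on the desk grid and are config
options, not calibrated quantities.  Reduced acquisition times (half = 4,
three-eighths = 3, quarter = 2 gates) are emulated by summing a per-view random
subset of gates — summing all gates reproduces the full-time data exactly.
Cardiac motion is deliberately absent: gates are i.i.d., which is the situation
the random per-view gate selection is designed to emulate.  Consequences: the
phantom reproduces count statistics and attenuation but not motion blur,
scatter, anatomical texture, or perfusion heterogeneity, so passing tests
demonstrate correct mechanics and plausible orderings, not clinical
performance levels.

## Reconstruction

Standard OSEM with stride-interleaved view subsets visited in index order,
uniform initialisation inside the body support, `eps = 1e-12` in the data
ratio, voxels with zero subset sensitivity frozen at zero, and a single 3D
Gaussian post-filter (FWHM 12.5 mm, sigma = FWHM/2.3548, reflective
boundaries) after the final pass.  Defaults: 16 subsets, 5 iterations.  With
one subset the update is MLEM and its Poisson log-likelihood is non-decreasing
on noise-free data, which the suite verifies.

## Patch lattice

Volumes are cropped into overlapping cubes on a stride lattice (training-scale
default 32^3 / stride 8).  The volume is zero-padded symmetrically so the
lattice covers every voxel; recombination averages overlapping patches with
inverse-distance weights `w = 1/(d + 0.5)` about the patch centre
`(s-1)/2` (the +0.5 voxel guard removes the centre singularity; the padding
margins are discarded).  Because all contributions to a voxel carry the same
value, `recombine(crop(v)) == v` exactly.

## Denoising models

All four architectures map a noisy patch to a denoised patch and are built on
an in-package numpy layer stack (channels-last conv3d via shift-and-matmul,
max-pooling, transposed convolution, dense, ReLU/LeakyReLU, Adam) with
hand-written backprop; training is float32, seeded, and bit-reproducible on a
fixed BLAS.

* **CNN** — 8 conv layers (8 filters, 3^3, ReLU) with additive skip
  connections between consecutive layers.
* **RES** — the CNN's blocks replaced by residual units
  (conv-ReLU-conv + identity, ReLU after addition; 4 units = 8 inner convs).
* **UNET** — 3 resolution levels (8/16/32 filters), two 3^3 convs + ReLU per
  level, 2x max-pool down, kernel-2/stride-2 transposed conv up, skip
  concatenation.
* **cGAN** — the UNET generator trained against a conditional discriminator
  (4 conv layers, 4^3 stride 2, LeakyReLU slope 0.2, then one fully connected
  sigmoid unit) that sees the candidate patch concatenated with its noisy
  input.

Every generator ends in a 1-channel projection conv plus a global
input-to-output residual; the projection is initialised at 0.1x the He scale
so an untrained model starts near the identity mapping and optimisation can
only improve on the noisy input.  CNN/RES/UNET minimise the L2 norm; the cGAN
generator minimises `L2 + lambda * BCE(D(G(x)), real)` with `lambda = 0.01`
(config-exposed; at `lambda = 0` the generator objective — and, at matched
seeds, its entire loss history — coincides with UNET's, because generator and
discriminator use independent RNG streams).  Optimiser: Adam at default
settings (lr 1e-3, betas 0.9/0.999); protocol-scale budget 100 epochs at batch
32.

Training pairs pool the half, three-eighths and quarter-time reconstructions
of every training study against the matching full-time reconstruction — one
model per strategy, never per acquisition time.  Reduced-time reconstructions
are first rescaled by `n_gates / n_selected` (duration normalisation): without
it a single pooled model would face an unidentifiable per-study intensity
scale.  Each pair is further divided by the study's mean full-time intensity
so the networks operate on O(1) values; whole-volume inference applies the
same normalisation, tiles the volume into overlapping patches, and recombines
with the inverse-distance weights, clipping at zero.

## Defect studies

A defect VOI is a seeded wall sector (40-90 degrees of angular extent,
30-60 % of the apex-base span) inside the myocardium mask.  Counts inside the
VOI of the *reconstructed* normal are reduced by the severity (presets 40 %
and 70 %); the removed counts are forward projected with the same system model
and subtracted from the acquisition data, clamped at zero, so one known lesion
is inserted consistently into the full/half/quarter-time projections of a
study.  The lesion projections are scaled by the acquisition-time fraction
before subtraction so the *relative* defect depth is identical at every time.
No Poisson re-noising is applied after subtraction (the acquisition data are
already noisy; re-noising would double-count).  Study bookkeeping: N normals x
1 VOI x 2 severities gives 2N defect studies per arm.

## Evaluation

* **Segmentation** (`threshold` mode) is a simplified LV wall tracker: a 50 %
  robust-max (99th percentile) blob, largest connected component, then — per
  short-axis slice whose peak reaches 90 % of the robust max — a per-sector
  radial-profile walk that keeps voxels above 75 % of the sector peak within
  9 mm of the peak radius; slices without a resolved cavity are treated as
  apex caps.  On a noise-free reconstruction that resolves the wall (3 mm
  grid, converged OSEM, no post-filter) it reaches Dice >= 0.8 against the
  phantom truth; at the clinical 4.8 mm / 12.5 mm-post-filter operating point
  the outline serves as a consistent measurement region rather than a
  voxel-accurate contour.
* **CoV** = 100 x sample sd / mean of masked voxels.
* **SSIM** is the whole-region, constant-free form
  `(2 mu_f mu_r/(mu_f^2+mu_r^2)) * (2 cov_fr/(var_f+var_r))` with sample
  (n-1) statistics; no sliding window.  Degenerate regions (both means or
  both variances zero) raise.
* **Polar maps** sample 12 rings (apex included) x 36 sectors by nearest-voxel
  ray marching from the mask centroid: the sample is the maximum masked count
  along the radial ray; rays that miss the mask (tolerated up to 5 %) are
  imputed from angular neighbours; each map is normalised to its own mean.
  Within one study all methods/times are mapped over the same mask (segmented
  from full-time OSEM) so scores compare like with like.
* **Normal databases** store per-sample mean and (n-1) sd over >= 2 normal
  maps, with the sd floored at 1 % of the mean level.
* **TPD** per sample: `z = (mean_db - value)/sd_db`, deficit
  `clip(z - z0, 0, zcap)/zcap`; TPD = 100 x mean deficit, used as the
  observer rating for ROC analysis.  The function's defaults are the
  clinical convention `z0 = 3`, `zcap = 4` (a clip-z simplification of
  clinical severity scoring).  The *benchmark profile* lowers the
  hypoperfusion threshold to `tpd_z0 = 1.5`: reconstruction blur dilutes a
  spec-sized VOI's 70 % count reduction to a ~20 % polar-map depth at desk
  resolution, while normal-map variability has an anatomy floor of ~0.07
  (relative), so at `z0 = 3` essentially no sample of any study crosses
  threshold and the score degenerates to zero for normals and defects alike.
  The lowered threshold is validated by the self-consistency requirement that
  members of a normal database average below 2 % TPD against their own
  database, which holds with margin.
* **ROC/AUC** via the Mann-Whitney statistic (ties 1/2) with DeLong standard
  errors; paired AUCs are compared with DeLong's placement-value covariance
  test.  **Paired t-tests** compare CoV/SSIM between methods, paired by
  phantom seed; all-zero differences give p = 1, zero-variance nonzero-mean
  differences are flagged degenerate (p = 0).

## Desk-scale profile

The package defaults run on a desk-scale budget chosen once: 48^3 grid
(4.8 mm voxels), 64 views, 3 training phantoms x 3 reduced times with
16^3/stride-12 patches (576 pairs), 4-5 epochs at batch 16-32, 10 test
phantoms, 8 normal-database phantoms, inference stride 12.  The
protocol-scale settings (128^3, 32^3/stride-8 patches, ~50k pairs, 100
epochs) remain the module-level defaults of the individual components and are
reachable through `ExperimentConfig`.  At desk scale the qualitative findings
are stable — CoV rises monotonically as acquisition time falls, every trained
model lowers CoV against matched-time OSEM, deeper defects score higher TPD,
and full-time detection is at least as good as quarter-time — but absolute
CoV/SSIM/AUC values depend on the phantom's simplifications and are not
calibrated against any clinical dataset.

## Numerical choices and edge cases

* Adjointness is exact by construction (sparse transpose; symmetric blur;
  diagonal attenuation), verified at 1e-6 in the suite.
* OSEM freezes voxels with zero subset sensitivity; all-zero projections give
  an all-zero reconstruction after the first update.
* `sum_gates` with all gates selected bypasses the RNG entirely.
* Defect VOI drawing retries (bounded) until the sector intersects the wall.
* Polar-map rings inset the mask's z-range by half a voxel; all-missing rings
  raise.
* Seeds: every stochastic step takes an explicit seed; arm seed ranges must be
  disjoint or the experiment config is refused.

## Known limitations

No scatter modelling, no motion, no anatomical background structure, no
CT-derived attenuation; the wall tracker is a simplification of clinical LV
surface fitting; TPD uses a clip-z severity model rather than the clinical
normal-limits pipeline; cGAN training is a minimal alternating scheme without
the stabilisation tricks larger frameworks apply.  The numpy training stack is
single-threaded BLAS-bound and intended for desk-scale budgets, not
production-scale training.
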