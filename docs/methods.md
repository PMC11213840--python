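# Methods

This note records the models, numerical choices and limitations behind
`sipspect`, in the order the pipeline runs them.

## Digital phantoms and kinetics

A phantom is a set of co-registered grids indexed `(x, y, z)` (0-based, z =
scanner axis): activity concentration in Bq/ml, linear attenuation at
208 keV in 1/cm, and boolean organ masks.  Anatomy is parametric rather
than anthropomorphic: an elliptic-cylinder body, two ellipsoidal kidneys
(default 150 ml each, axis ratio 1.8, with one re-voxelisation step so the
discrete volume tracks the request), a posterior vertebral column of
stacked cylinders (28 mm bodies, 4 mm disc gaps, 14 mm radius) with an 8 mm
marrow cavity, 4-ml marrow sphere VOIs at vertebra centroids, and optional
spherical lesions.  Attenuation: soft tissue 0.137 cm⁻¹, bone 1.4× soft
tissue, air 0 — configurable, since real systems derive µ from CT.

Organ kinetics are biexponential, C(t) = A₁e^(−λ₁t) + A₂e^(−λ₂t) (Bq/ml,
1/h).  Defaults were chosen once as plausible therapy kinetics: kidney
(A₁ = 2×10⁵, λ₁ = 0.06, A₂ = 4×10⁴, λ₂ = 0.008) dominates, vertebra/marrow
uptake is an order of magnitude lower, and whole-body count levels fall
monotonically over the four imaging times (2, 24, 48, 168 h).  No clinical
concentration tables back these numbers; they set realistic count levels
and contrasts, nothing more.  Background activity carries a multiplicative
lognormal texture (CV 0.1) whose mean over the background is normalised to
exactly 1, so total activity remains an exact sum of per-region
volume × concentration; masks depend only on the configuration, the seed
moves only the texture.

## Projector

The system model is a rotation-based projector.  Per view the volume and
µ-map are rotated by a precomputed sparse bilinear-interpolation operator
(volume rotates, detector stays), each constant-depth plane is blurred with
a Gaussian whose sigma grows linearly with distance to the detector
(σ(d) = σ₀ + s·d; defaults σ₀ = 2 mm, s = 0.04, representative of a
medium-energy collimator rather than a measured response), every voxel is
weighted by exp(−∫µ dl) integrated in voxel-length steps (half length for
the emitting voxel), and rays are summed.  Counts scale as
activity × voxel volume × sensitivity (10 cps/MBq) × frame duration (30 s).

Three numerical choices matter:

* **Exact adjointness.**  The back projector applies the transposed pieces
  in reverse order.  Rotation is a stored sparse matrix (transpose exact),
  attenuation is diagonal, and the PSF is applied as a per-plane periodic
  convolution via FFT with a real symmetric Gaussian transfer function —
  self-adjoint by construction.  The inner-product identity holds to
  machine precision, which is what makes the multiplicative EM update
  well-behaved.  The price of the FFT route is periodic wrap-around of
  blur tails across the field-of-view edge; objects keep a margin inside
  the FOV, and simulation and reconstruction share the operator, so no
  inconsistency is introduced.  Clipping of ~10⁻¹⁶-relative negative FFT
  roundoff is applied only where a count stack is exposed.
* **Scatter** is not modelled separately; the depth-dependent Gaussian is
  the entire resolution model.
* **Noise** lives only in `add_poisson_noise` (seeded, per-pixel Poisson),
  never inside the projectors, so operator tests stay exact.

A photon-sampling mode (`mc_forward_project`) estimates the same projection
stochastically: each voxel emits a configurable number of weighted photons
(default 200/voxel) with transaxial and axial tilts uniform in ±0.06 rad
around the detector normal, carrying the attenuation survival of the axial
path (small-angle approximation) and tallied at the pixel the tilted path
reaches.  Its expectation approaches the analytic projector without PSF as
the photon count grows; it exists for fidelity experiments, not as the
default reconstruction model.

## Synthetic intermediate projections

Down-sampling keeps every fourth view starting with the first (1-based
indices 1, 5, …, 117).  Each angular offset (1, 2, 3) gets its own network
mapping the full 30-view stack (treated as image channels) to the 30 views
at that offset; the three outputs interleave with the acquired views into a
120-view set whose provenance flags mark exactly the 30 acquired ones.

The network is a three-level encoder–decoder with skip connections (8 base
channels, 3×3 convolutions, ReLU, average pooling, nearest-neighbour
upsampling, 1×1 output head), implemented directly in numpy with im2col
convolutions, manual backpropagation and Adam (lr 10⁻³).  Being pure
numpy, training is bit-reproducible for a fixed seed on one machine.  Two
design choices are worth flagging:

* **Residual prediction.**  The net predicts a correction *on top of* the
  angle-linear interpolation baseline (weights (4−o)/4 and o/4 on the
  neighbouring acquired views, last gap wrapping around 360°).  The output
  head starts near zero, so an untrained model already produces sensible
  views and training spends its budget on what interpolation gets wrong —
  mostly carrying neighbour noise into the synthetic view.  This is
  standard restoration-network practice and is what lets desk-scale
  training (20 phantoms, 20 epochs) reach and pass the baseline.
* **Normalisation.**  Each sample is scaled by its sparse stack's maximum
  before the network and unscaled after, because count levels differ by
  ~20× between day 0 and day 7 and one model must serve all of them.
  Outputs are clamped to ≥ 0 (counts).

L1 and L2 losses are both available; L2 is the default used in the driver.
Training targets are the *noisy* acquired views at the offset, so the
network learns a conditional mean and effectively denoises.

## Reconstruction

Standard OSEM: x ← x · back_s(y_s / fwd_s(x)) / back_s(1), angularly
interleaved subsets (subset k takes view indices ≡ k mod subsets), default
10 iterations × 6 subsets, subsets = 1 giving classical MLEM.  The initial
estimate is uniform-positive on the attenuation support (µ > 0), falling
back to the whole grid when µ carries no support; 0/0 ray ratios are 0, and
a data>0/model=0 ratio is capped at 10⁶ to keep the update finite.  No
post-filter is applied.  Per-angle rotators and attenuation weights are
cached across all iterations and subsets.  `calibrate` turns
counts-proportional values into Bq/ml using the eroded core of a uniform
region of a known phantom; calibration factors are computed per
reconstruction method so the 4× count difference between sparse and full
sets is absorbed there rather than normalised inside the reconstruction.

## Image-quality measures

NRMSE and NMAE normalise by the mean reference value, making error
magnitudes comparable across time points; PSNR = 20·log₁₀(MAX/RMSE) with
MAX the maximum over both images (+∞ reported for identical images); SSIM
uses the standard stabilised form with c₁ = (0.01L)², c₂ = (0.03L)², L the
reference dynamic range.  SSIM is computed with single image-wide moments
by default — the formula as written in terms of global means, variances
and covariance — with the conventional sliding-window variant available
behind a flag (`windowed=True`, via scikit-image).  Metrics run over the
full arrays, background included, with no cropping.

## Dosimetry

Per organ and reconstruction method: VOI mean concentration at each of the
four time points → biexponential fit → analytic 0→∞ integral
TIA = A₁/λ₁ + A₂/λ₂ → absorbed dose under local electron energy deposition
(photon dose neglected).  Dose conversion uses a mean electron energy of
147.9 keV per decay (ICRP-107 total electron energy for ^177^Lu; a config
constant, not code) and densities 1.05 g/ml (kidney) / 1.00 g/ml (marrow
fluid).  1 MBq·h/ml in kidney tissue is 0.0812 Gy under these constants.

Kidney concentrations are corrected by a per-method recovery coefficient:
the kidney VOI is filled with a uniform known concentration in a cold
attenuating body, the full acquisition is simulated noiselessly, the
method's projection set is built and reconstructed, and RC = recovered VOI
mean / truth.  One RC per method is reused for every subject and time
point.  Marrow uses 4-ml sphere VOIs with RC = 1; vertebral concentrations
are divided by the red-marrow volume fraction 0.57 and the dose carries the
absorbed fraction 0.65.

The biexponential fit is deterministic: a fixed λ-pair grid
(14 log-spaced values, λ₁ > λ₂) is screened with amplitudes solved
linearly, the three best starts are polished by bounded least squares in
(A₁, A₂, ln λ₁, ln λ₂), and the fit must stay nonnegative on [0, 2t_max]
with a positive integral.  Unweighted least squares is the default;
four noiseless samples are recovered to better than 0.1 %.

## What the closed loop shows — and its known bias

With noiseless data, a consistent projector and the full pipeline
(calibration → RC → fit → integral → dose), the recovered kidney dose on
the default 64×64×48 phantom lands ~5.5 % *below* the analytic dose implied
by the generating kinetics.  The cause is measurable and reproducible: RCs
determined in a cold background overestimate recovery in a warm one.  In
the cold RC simulation the nonnegativity constraint of EM pushes all
spill-out back into the only positive structure, giving RC ≈ 0.88 at
10 it × 6 subsets, while the same reconstruction of the kidney embedded in
warm background recovers only ≈ 0.83 of the true concentration; the ~6 %
gap persists essentially unchanged from 10 to 80 iterations, so it is a
property of the fixed point under the constraint, not of stopping early.
Single-RC partial-volume correction inherits this bias by construction.
It is reported, not hidden: the closed-loop check in the test suite asserts
a 5 % bound and currently fails at 5.5 %, and `scripts/acceptance.py`
prints the measured closed-loop error.

## Statistics

Method agreement uses Bland–Altman relative differences,
100·(a−b)/((a+b)/2), with limits of agreement mean ± 1.96·SD (a CI of the
mean is available behind a flag); left and right kidneys count as separate
observations.  Concordance uses OLS with R²; paired comparisons use
dependent-samples t-tests at the Bonferroni level 0.05/4 = 0.0125 (all-zero
differences give p = 1, zero variance with nonzero mean is floored at
10⁻¹²); repeated-measures tables use classical one-way within-subject
ANOVA (F = t² for two methods).

## Desk-scale problem sizes

Chosen once as the package defaults: headline experiment on 64×64×64 grids
at 4.42 mm (projections 64×64, 120 views), 20 jittered training phantoms at
the day-1 count level (mirroring that almost all clinical training material
comes from day 1), 20 training epochs, one held-out phantom at four time
points; noise-propagation study on 32³ grids with 40 base views and 20
Poisson replicates; closed-loop dosimetry on the default 64×64×48 phantom.
The clinical 128×128 matrix is supported but slower.

## Limitations

* Anatomy is parametric; no respiratory motion, no CT-derived µ, no
  anthropomorphic texture.  Passing tests show pipeline correctness and
  directional behaviour, not clinical accuracy.
* Scatter and septal penetration are folded into one Gaussian PSF.
* The PSF parameters are representative, not a measured collimator
  characterisation.
* The photon-sampling projector approximates attenuation along the axial
  path (valid for the small default angular range).
* Marrow-sphere VOIs in the small synthetic spine see heavy spill-in from
  surrounding background, so absolute marrow doses are biased high;
  method-to-method comparisons, which share the bias, remain meaningful.
* A 4-ml sphere at 4.42 mm voxels quantises to 33–56 voxels depending on
  centre alignment; volume-accurate VOIs need finer grids.
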