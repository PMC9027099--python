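# Methods

This package turns through-plane interpolation of volumetric medical
images into a learned super-resolution (SR) problem.  This note records
the model, the simulated acquisition physics, the training procedure, the
design choices that were genuinely open, and what the desk-scale phantom
experiments do and do not demonstrate.

## Problem and model

A clinical 3D acquisition trades through-plane (z) resolution for time:
slices are thick (partial-volume averaging) or sparsely spaced (aliasing
in reformats).  Reconstruction of the thin-slice volume x from the
observed y is modelled as a linear encoding `E x = y + eps`, where E is an
anti-aliasing filter followed by s-fold decimation along z, and eps is
measurement noise (default 0).  The SR network learns the inverse mapping
from (LR, HR) pairs obtained by *simulating* E on high-resolution volumes.

The generator is a **pre-upsampling residual CNN**: the LR volume is first
interpolated to the target grid with cubic splines, and the network adds a
learned residual correction.  Untrained, the network is exactly the
identity (the final exit convolutions are zero-initialized), so the
pipeline degrades gracefully to tricubic interpolation (TCI) - the
baseline any SR output is compared against.

**Scale attention.**  One model serves any factor s in [1.5, 6.5].  Per
trained integer scale s_i in {2, 3, 4, 5, 6} the network has a small entry
and exit convolution branch; everything between - the residual backbone -
is shared.  For a requested s the branch outputs are mixed by alignment
weights alpha(s): one-hot at trained integers, linear cross-fade
(1 - t, t) between the two bracketing branches for fractional s, clamped
one-hot outside [2, 6].  alpha is continuous and piecewise linear in s,
with at most two adjacent nonzero entries.

**Degradation criteria.**  Two acquisition regimes are simulated:

* *thick-to-thin*: moving-average FIR filter of length s (coefficients
  1/s) along z, then phase-0 decimation - the partial-volume averaging of
  thick slices; intrinsically anti-aliased.
* *sparse-to-thin*: plain decimation, no filter - sparsely stacked 2D
  slices; aliasing in perpendicular planes is intended and preserved.
* a Gaussian slice profile (tunable sigma, truncated at 4 sigma,
  renormalized) covers intermediate protocols.

**Grid alignment.**  Decimation is phase-0 (first output slice = first
input slice/block) and the pipeline's cubic regridding is phase-0 as
well: output slice p is the spline evaluated at input coordinate p / s,
so retained sparse slices reappear exactly at output indices 0, s, 2s,
... (asserted as an invariant) and the LR-to-HR mapping is exactly
s-periodic.  Periodicity matters: it makes every systematic component of
the interpolation residual translation-invariant and therefore
representable by a convolutional network.  An endpoint-aligned grid
(first and last samples pinned to the input ends; the default of the
standalone resampling function, matching its documented examples) instead
produces a z-dependent stretch of up to (s-1)/2 slices that no
translation-equivariant model can express; measured on the phantom
corpus, training under that grid never improved on the identity.

**Losses.**  Stage 1 trains the generator with voxelwise MSE.  Stage 2
fine-tunes with `L_G = L_per + lambda L_GAN + mu L_MSE` (lambda = 0.01,
mu = 0.001).  The perceptual term generalizes 2D feature losses to
volumes *tri-axially*: all axial, sagittal and coronal planes of both
volumes (3n slices for an n^3 patch) pass through a 2D feature extractor
and squared feature differences are averaged over slices and feature
dimensions, so the loss is independent of patch size.  The adversarial
term is a vanilla GAN (sigmoid discriminator, log losses); the generator
uses the non-saturating form -log D(G(y)), which shares fixed points with
the min-max form but avoids vanishing early gradients.

**Feature extractor.**  The extractor is injectable behind a small
contract (normalize / apply / apply_backward).  The package default is a
fixed-seed, untrained two-layer convolutional embedding ("random
features").  Random deep features induce a valid perceptual metric - zero
iff feature maps agree, symmetric, deterministic - and require no
downloaded weights; a pretrained embedding can be plugged in through the
same contract.  Grayscale slices are replicated to three channels and
divided by the standardization ceiling before embedding.

## Intensity standardization

Each volume is min-max mapped to the window (0, 10000) before any
network sees it; the window is recorded and invertible.  A fixed window
makes one model usable across modalities with wildly different native
scales (MRI arbitrary units, CT Hounsfield units) and fixes the
`data_range` of PSNR/SSIM so scores are comparable across volumes.
Per-volume extrema (not percentile clipping) are used - the simplest
reading, recorded so it can be inverted.

## Numerical engine

The 3D/2D convolutions, their gradients and the Adam optimizer are
implemented in NumPy with numba-compiled direct-convolution kernels
(channels-first, contiguous inner loop; stride-1 3-tap path specialized).
A direct convolution outperforms im2col + GEMM here because the 27-fold
im2col gather is memory-bandwidth-bound.  Input gradients are computed as
transposed convolutions through the same forward kernel; all gradient
paths are verified against central finite differences in the test suite.
Computation is float32; reductions in loss computations are float64.

Two internal scalings keep optimization well conditioned while the
interface speaks standardized intensity units: network inputs are divided
by the ceiling (10^4), and the generator's residual is emitted at one
tenth of the ceiling (residual scaling, the standard stabilization for
residual SR networks).  Both cancel exactly for the zero-initialized
network, preserving the untrained-equals-TCI identity bitwise.

## Training procedure

* Adam, beta = (0.9, 0.999); stage-1 learning rate 3e-4.
* Plateau schedule: when the validation loss fails to improve (relative
  tolerance 1e-6) for `plateau_patience` consecutive cycles (cycle = one
  epoch), the rate is divided by 3; after three such plateau events the
  stage is complete.  Patience defaults to 3 cycles: with few optimizer
  steps per epoch (small corpora) single-epoch non-monotonicity is
  routine, and patience 1 was observed to decay the rate 27x within the
  first few epochs, freezing the model near its initialization.
* Batches are scale-homogeneous (one alpha per forward pass); batch
  size 16.
* Stage 1 returns the best-validation snapshot rather than the last
  epoch's parameters: on small corpora the final epochs routinely drift
  past the best generalizing model.
* Stage 2 runs the generator at a fixed 1e-4 (smaller than the stage-1
  initial rate, standard for fine-tuning) and the discriminator at 3e-4
  (two-time-scale updates: D must track a slowly changing G), with a
  fixed epoch/batch budget; all loss terms are persisted per batch, since
  visual convergence is not automatable and the curves are left for
  inspection.
* Checkpoints are single-file archives (parameters + config + stage tag).

## Phantoms: what they emulate and what they do not

Training and testing run on procedural phantoms: a low-order polynomial
background (smooth gradients), randomly placed ellipsoids with constant
interiors (sharp boundaries through-plane - the content interpolation
blurs and SR must restore), and band-limited Gaussian random texture
(fine detail with measurable energy above the decimation Nyquist).
Everything is deterministic per seed and standardized to (0, 10000).

Texture amplitude matters for what the benchmark can show: texture energy
*above* the LR Nyquist is information destroyed by decimation - an
irreducible error floor shared by every method.  If that floor dominates,
SR and interpolation become indistinguishable by construction.  The
default texture is therefore mild and fairly smooth, so that the
recoverable structure (ellipsoid edges) dominates the residual and
SR-versus-TCI differences are measurable.

Phantoms are not anatomy: no tissue classes, no MR physics, no bias
fields, no motion.  Passing desk-scale tests shows the pipeline learns to
invert its own degradation model on structured volumes and beats
interpolation there; it does not certify clinical image quality.

## Desk-scale study conditions

The full-size generator (14 backbone convolutions, 64 channels) is the
package default.  Desk-scale experiments - the test suite and the
acceptance script - use a reduced generator and a small corpus chosen so
stage-1 training completes in minutes on one CPU: 10 phantoms of 64^3
(split 8:1:1 at phantom level), thick-mode degradation at s = 4,
non-overlapping 32^3 patches (8 per phantom), batch 16, at most 30
epochs.  Problem sizes are stated alongside each reported number.

## Known limitations

* Under the phase-0 convention a thick-slice sample (the mean of s thin
  slices) is anchored at its block's first slice rather than its centre,
  so the tricubic baseline carries a constant (s-1)/2-slice offset for
  thick-mode inputs.  The offset is part of the encoder being inverted
  and the trained network learns to remove it; comparisons against TCI
  therefore mix deblurring and phase correction.  Centre-anchored
  regridding would remove the offset from both methods at the cost of
  breaking the exact sparse-slice fidelity the pipeline guarantees.
* The desk-scale optimizer budget (~10^2 steps) is orders of magnitude
  smaller than practical SR training; the reduced model underfits
  accordingly.
* The random-feature perceptual loss is a valid metric but not a learned
  semantic one; stage-2 results demonstrate mechanics (stability,
  direction), not perceptual quality.
* Fractional factors at inference rely on branch interpolation; no
  fractional-factor degradation is simulated in training.
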