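# thinsr

Through-plane super-resolution for volumetric medical images: a
scale-attention residual 3D CNN that replaces conventional slice
interpolation with a learned reconstruction, for any upsampling factor
s in [1.5, 6.5].

## Who this is for

Clinical 3D acquisitions (MRI, CT) usually have much coarser resolution
through-plane (z) than in-plane: slices are thick or widely spaced to
keep scan time reasonable.  Anyone producing thin-slice volumes from such
data - for multiplanar reformats, registration, radiomics, or data
augmentation - typically reaches for tricubic interpolation (TCI), which
blurs edges and cannot restore detail.  `thinsr` trains a generative
model to do that interpolation better, and exposes it as a drop-in tool:
NIfTI in, NIfTI out, any factor in [1.5, 6.5].

## The model

Reconstruction is posed as inverting a linear encoder `E x = y + eps`:
the observed LR volume y is the HR volume x filtered along z and
decimated by a factor s.  Two simulated acquisition regimes provide
training pairs:

* **thick-to-thin** - length-s moving-average FIR (coefficients 1/s),
  then s-fold decimation: partial-volume averaging of thick slices;
* **sparse-to-thin** - plain s-fold decimation: sparsely stacked thin
  slices, aliasing preserved.

The generator G_theta is a *pre-upsampling residual* network: the input
is first cubically interpolated to the target grid and the network
predicts a residual correction.  Per trained scale s_i in {2, 3, 4, 5, 6}
it has small entry/exit convolution branches around a shared residual
backbone (default 14 conv layers, 64 channels); for a requested factor s
the branches are mixed by alignment weights

    alpha = [1, 0, ..., 0]                    s < 2
            [0, ..., 1 - t, t, ..., 0]        m <= s < m + 1,  t = s - m
            [0, ..., 0, 1]                    s >= 6

so one model covers the whole range continuously.  Training is
two-stage: (1) voxelwise MSE with Adam (lr 3e-4, plateau-divided by 3,
three decays then stop); (2) fine-tuning with
`L_G = L_per + 0.01 L_GAN + 0.001 L_MSE`, where L_per is a *tri-axial*
perceptual loss - all axial, sagittal and coronal slices of prediction
and truth pass through a 2D feature extractor and squared feature
differences are averaged - and L_GAN is a vanilla adversarial loss
against a 3D patch discriminator.  Untrained, the generator is exactly
the identity, so its output equals tricubic interpolation - the baseline
it must beat.  Details and design rationale: `docs/methods.md`.

The neural network layer (3D/2D convolutions with backprop, Adam) is
implemented in NumPy with numba-compiled kernels; no GPU or deep-learning
framework is required.

## Worked example

Everything runs on procedurally generated phantoms (smooth gradients,
sharp ellipsoids, band-limited texture), so no data download is needed:

```sh
soup phantom --n 10 --shape 64,64,64 --seed 0 --out phantoms/
soup prepare --hr-dir phantoms/ --out corpus/ --modes thick --factors 4 \
     --patch 32 --ratios 0.8,0.1,0.1 --seed 0
soup train --corpus corpus/ --stage mse --config examples/train.yaml \
     --out g_mse.npz --seed 0
# phantom-001 is the held-out test phantom of this split (see
# corpus/manifest.json)
soup degrade --in phantoms/phantom-001.nii.gz --out lr.nii.gz --mode thick --factor 4
soup infer --in lr.nii.gz --out sr.nii.gz --factor 4 --ckpt g_mse.npz
soup eval --sr sr.nii.gz --truth phantoms/phantom-001.nii.gz --json report.json
```

With the desk-scale generator of `examples/train.yaml` (4 backbone conv
layers, 8 channels; ~5 min of training on one CPU) the final `soup eval`
prints, for the held-out phantom at s = 4 (values shown to 1-3 digits):

```json
{
 "patient_id": "sr.nii.gz",
 "s": 0.0,
 "method": "sr",
 "rmse": 281.1,
 "psnr": 31.02,
 "ssim": 0.873
}
```

against `rmse 337.3, psnr 29.4, ssim 0.854` for plain tricubic
interpolation of the same input (evaluate it by running `soup infer` with
an untrained checkpoint, which is exactly TCI).  Intensities are on the
standardized (0, 10000) scale: the trained model cuts the reconstruction
error by roughly a sixth and improves structural similarity - at desk
scale, with minutes of CPU training.  The full-size configuration is the
library default for real training runs.

## Layout

```
src/thinsr/         volume_io, degrade, dataset, model, losses,
                    training, inference, metrics, phantom, cli, nn/
tests/              pytest suite (unit, property, acceptance)
docs/methods.md     model, assumptions, parameters, limitations
scripts/acceptance.py
examples/train.yaml desk-scale training configuration
```
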