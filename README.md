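# mrupsample

Single-image upsampling for 3-D MR volumes by **second-order patch
regression**. Clinical MR acquisitions are routinely anisotropic (e.g.
1 × 1 × 6 mm³): scan time is saved by acquiring fewer, thicker slices, and
many downstream analyses then need an isotropic volume. Classical
interpolators (nearest-neighbour, trilinear, spline) and their
nonlocal-means refinements estimate each unknown voxel as a *weighted
average* of observed voxels — a zeroth-order local model that blurs the
laminar structures of brain anatomy. This package models the
low-resolution → high-resolution mapping one step further.

## Method

The acquired LR volume is modelled as `Y = DHZ + η` (blur `H`, block
downsampling `D`, Rician noise `η`). Writing `I` for the (denoised) LR
input, two scale spaces are built: `Z_s`, a bicubic upscaling of `I` onto
the target grid, and `I_s`, a re-blurred `I` (bilinear down/up-sampling).
Cross-scale self-similarity makes `{I_s → I}` patch pairs examples of the
same blur-inverting mapping `f` that must carry `Z_s → Z`.

For each s × s query patch **q**ₛ of `Z_s` (s = 2r+1, default 5), the most
similar reference patch **p**ₛ is found in `I_s`, and `f` is expanded to
second order around it:

```
q̂ = p + f′(pₛ) ∘ (qₛ − pₛ) + ½ f″(pₛ) ∘ (qₛ − pₛ) ∘ (qₛ − pₛ)
```

The element-wise derivative vectors `f′, f″` are fitted by weighted least
squares over the J most similar patches per slice, gathered from *p*
neighbouring slices (defaults v = 11 search radius, r = 2, p = 5, J = 11 —
55 training pairs against the 50 unknowns). Patch similarity is measured
with 3 × 3 region covariance descriptors of (intensity, ∂I/∂x, ∂I/∂y)
features, compared through their generalized eigenvalues:
`w = exp(−Σⱼ ln² λⱼ)`. The stacked design decouples per pixel, so each fit
reduces to n independent 2 × 2 solves. Overlapping predictions are
averaged and a mean-correction step forces every zoom-block of the output
to average back exactly to its LR voxel.

The package also ships the acquisition simulator (Gaussian blur σ = 0.8,
integer block downsampling, Rician noise at a chosen fraction of the
maximum intensity), a brain-like synthetic phantom generator, and the
PSNR / SSIM / mutual-information metrics used to score reconstructions.

## Worked example

```python
import mrupsample as m

gt = m.make_phantom((64, 64, 64), seed=7)            # ground truth, [0, 1]
lr = m.degrade(gt, m.DegradeConfig(sigma=0.8, factors=(2, 2, 2)))
hr = m.upsample_volume(lr, m.UpsampleParams(zoom=(2, 2, 2), stride=2))
tri = m.baseline_upsample(lr, (2, 2, 2))             # trilinear reference

print(f"proposed : PSNR {m.psnr(gt, hr):.2f} dB  SSIM {m.ssim(gt, hr):.4f}")
print(f"trilinear: PSNR {m.psnr(gt, tri):.2f} dB  SSIM {m.ssim(gt, tri):.4f}")
```

prints (deterministically, for this phantom seed):

```
proposed : PSNR 22.76 dB  SSIM 0.8666
trilinear: PSNR 20.10 dB  SSIM 0.7802
```

The reconstruction recovers ~2.7 dB of the detail the trilinear baseline
leaves blurred, and its structural similarity to the ground truth rises
accordingly. By construction, `m.block_downsample(hr, (2, 2, 2))` returns
the LR input to machine precision — the output never contradicts what was
actually measured.

The same pipeline is available from the shell:

```bash
mrup degrade --sigma 0.8 --factors 2,2,2 --noise 0.03 --seed 5 hr.nii.gz lr.nii.gz
mrup upsample --zoom 2,2,2 --v 11 --r 2 --slices 5 --J 11 lr.nii.gz up.nii.gz
mrup evaluate hr.nii.gz up.nii.gz
```

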