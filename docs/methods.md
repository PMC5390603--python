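# Methods

## Model

An acquired low-resolution (LR) magnitude MR volume is modelled as
`Y = DHZ + η`: the underlying high-resolution (HR) anatomy `Z` convolved
with a 3-D Gaussian point spread `H` (σ in voxel units), block-averaged by
integer per-axis factors `D` (the slice-thickness model: each thick voxel
is the mean of the thin voxels it covers), plus Rician noise `η`
(`sqrt((x+n₁)² + n₂²)` with i.i.d. Gaussian `n₁, n₂`, the magnitude
statistics of complex k-space noise). Upsampling inverts this map given
only `Y` — or rather its denoised version `I`; the package assumes the
input is noise-free or pre-denoised, with an optional Gaussian pre-filter
hook (`prefilter_sigma`) for mildly noisy inputs.

The inverse blur is treated as an unknown mapping `f` learned locally.
Two scale spaces are built from `I`:

* `Z_s` — bicubic (cubic-spline, voxel-center-aligned) interpolation of
  `I` onto the zoomed grid; the query domain.
* `I_s` — `I` bilinearly downsampled by the zoom factors and bilinearly
  upsampled back; the training domain. `{I_s → I}` patch pairs exemplify
  the smoothed→sharp relation one scale below `{Z_s → Z}`.

For a query patch `q_s` (s×s, s = 2r+1, vectorized row-major) the mapping
is expanded to second order around the most similar reference patch `p_s`
of `I_s`:

```
q̂ = p + f′ ∘ Δ + ½ f″ ∘ Δ ∘ Δ,   Δ = q_s − p_s
```

with `p` the same-center patch of `I` and `f′, f″` element-wise derivative
vectors. Each training pair `(p_i,s, p_i)` contributes, per pixel `j`, the
observation `p_i[j] − p[j] ≈ f′[j]·d + f″[j]·d²/2` with `d = p_i,s[j] −
p_s[j]`, weighted by the pair's similarity weight; the stacked weighted
least squares decouples into n independent 2×2 solves (verified in the
tests against the dense normal-equation solve). Second order is the
sweet spot: first order cannot bend the mapping, higher orders multiply
the unknowns (already 2·(2r+1)² = 50 at r = 2) beyond what 
`p × J = 55` local training pairs support.

## Patch similarity

A patch is summarised by the 3×3 covariance of its per-pixel features
`(I, ∂I/∂x, ∂I/∂y)` (gradients by central differences, one-sided at
borders), regularized by `ε·Id` with ε = 1e-8 on [0,1]-normalized
intensities so constant patches stay positive definite. Similarity is
`w = exp(−Σⱼ ln² λⱼ)` over the three generalized eigenvalues of the
descriptor pair — symmetric, 1 iff the descriptors coincide, and invariant
to global intensity scaling. Searches are exhaustive within a radius-v
window (HR centers are mapped to LR coordinates by dividing by the zoom
and rounding); exact ties break to the smallest (row, col), which makes
the whole reconstruction deterministic. Slices are mirror-padded by r so
every pixel is a valid patch center. The per-slice search index computes
all descriptors by box-filtered moments and all pencil eigenvalues by the
closed-form (Cardano) symmetric 3×3 solution after Cholesky whitening;
both routes are cross-checked against direct summation and LAPACK in the
tests.

## Parameters

| name | default | meaning |
|------|---------|---------|
| `v` | 11 | search-window radius (voxels); larger finds better matches, costs quadratically |
| `r` | 2 | patch radius → 5×5 patches, 50 derivative unknowns |
| `p_slices` | 5 | neighbouring slices searched for training pairs (clipped at volume ends) |
| `J` | 11 | training patches kept per slice; 5 × 11 = 55 > 50 equations |
| `stride` | 1 | patch-center step on the HR lattice; endpoints always included, any stride ≤ 2r+1 covers every voxel |
| `ridge` | 1e-6 | relative Tikhonov term per pixel (fraction of the mean normal-matrix diagonal) |
| `ridge_floor` | 1e-3 | absolute Tikhonov floor on [0,1-]normalized intensities (see below) |
| `sigma` (simulator) | 0.8 | acquisition blur, voxel units |
| `noise_level` | 0…0.09 | Rician σ as a fraction of the volume maximum |

## Numerical choices

* **Ridge floor.** The relative ridge alone leaves the 2×2 solves
  well-conditioned but does not bound the derivative *magnitude*: in
  near-flat regions the training offsets carry almost no energy, the
  fitted `f′, f″` become noise quotients of order 10²–10³, and the
  quadratic term extrapolates them to query offsets far outside the
  training range — isolated voxels then land at ±80 on [0, 1] data. The
  absolute floor (1e-3) shrinks exactly those ill-determined coefficients
  toward zero, degrading gracefully into the zeroth-order patch copy
  `q̂ = p`; where structure is present the normal-matrix diagonal is
  orders of magnitude larger and the floor is inert.
* **Range clamp.** Accumulated predictions are clamped to the normalized
  [0, 1] range *before* mean correction; a Taylor extrapolation outside
  the observed intensity range is never trustworthy. `predict_patch`
  itself stays unclipped. Mean correction runs last, so the block-mean
  identity with the LR input holds exactly in the final output.
* **Degenerate pixels.** All-zero offsets (or a numerically singular 2×2
  system) yield `f′ = f″ = 0`, i.e. patch copy.
* **Normalization.** Intensities are min-max normalized per volume before
  feature computation, making ε, ridge and clamp scale-free; the output is
  mapped back to the native range. A zero-range (constant) volume
  short-circuits to the constant HR volume.
* **Boundary handling.** Mirror reflection everywhere (blur kernel,
  patch padding). The blur kernel is truncated at ±4σ and renormalized;
  constants are exact fixed points. Note mirror boundaries conserve the
  global mean only for interior-supported data.
* **Downsampling dialect.** "Downsampling" is block averaging, not
  decimation: it is the standard slice-thickness model and composes
  exactly with mean correction (block means of the reconstruction equal
  the LR input to ~1e-16).
* **Eigenvalue count.** The similarity exponent sums over the 3
  generalized eigenvalues of the 3×3 descriptor pencil — the only
  mathematically possible count for this feature dimension.
* **Reference search scope.** The reference patch is sought in the
  corresponding slice of `I_s` only; neighbouring slices contribute
  training pairs. One pass, no iteration.

## Synthetic phantom

`make_phantom` emulates the three image traits the method exploits:
nested ellipsoidal shells (laminar anatomy → strong cross-slice and
cross-scale patch recurrence), a smooth intensity ramp (partial-volume /
bias-like slow variation), and band-limited texture (fine tissue
contrast that survives mild blurring). It does **not** emulate real
acquisition artifacts — bias fields, motion, ghosting, non-Gaussian slice
profiles — nor true anatomical variability, so passing the phantom
harness demonstrates that the machinery works under the model's own
assumptions, not clinical performance. Phantoms are deterministic given
their seed.

## Problem sizes and evaluation

The end-to-end harness uses a 64³ phantom, σ = 0.8 blur and 2×2×2 block
downsampling, reconstructed at stride 2 — small enough for routine runs
(about 1.5 minutes on one CPU) while leaving dozens of informative slices;
stride 1 roughly quadruples the cost for a few tenths of a dB. Scores:
PSNR (dB, reference dynamic range), SSIM (11×11 Gaussian windows,
σ = 1.5, K1 = 0.01, K2 = 0.03, computed per axial slice and averaged) and
mutual information (64 equal-width bins per volume, log base 2, in bits —
conventions recorded in `MetricsReport`; MI values are convention-dependent
and not comparable across implementations). On this harness the
second-order reconstruction beats trilinear interpolation by ≈ 2.7 dB
PSNR and ≈ 0.09 SSIM.

## Known limitations

* Noise is not handled jointly: the regression assumes a denoised input,
  and the Gaussian pre-filter hook trades detail for robustness.
* Non-integer zoom factors are rejected (mean correction requires integer
  blocks).
* The covariance descriptor ignores the DC level of a patch, so the
  reference match can sit at a different mean intensity; the first-order
  term compensates only where the derivatives are well determined.
* `Z_s` (HR-grid) and `I_s` (LR-grid) patches are compared at different
  physical scales; the descriptor pencil metric absorbs a global feature
  scaling but not the differing intensity/gradient scale ratio, a bias
  inherited from the cross-scale design.
* Exhaustive windowed search only; no approximate nearest-neighbour
  acceleration, no GPU path, no multi-modal guidance.
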