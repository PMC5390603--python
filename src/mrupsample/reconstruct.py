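"""Patch-wise volume reconstruction.

Single-image upsampling, one pass, no external training data.  Given a
(denoised) low-resolution volume I and integer per-axis zoom factors:

1.  Build two scale spaces: Z_s, a bicubic upscaling of I onto the target
    grid (the query domain), and I_s, a re-blurred I made by bilinear
    down- then up-sampling (the training domain).  The pairs {I_s -> I}
    exhibit the smoothed->sharp relation that {Z_s -> Z} must undergo.
2.  For every patch q_s of every axial slice of Z_s, find the most similar
    reference patch p_s in the corresponding slice of I_s, gather the J
    most similar training patches per slice over a band of neighbouring
    slices, fit the element-wise second-order Taylor derivatives of the
    mapping by weighted least squares, and predict the sharp patch
    q_hat = p + f1 o (q_s - p_s) + 1/2 f2 o (q_s - p_s)^2.
3.  Average overlapping predictions, then apply a mean-correction step so
    that every zoom-block of the output averages back exactly to its LR
    voxel — consistency with the block-averaging acquisition model.

Patches are 2-D in-plane (axis 0 is the slice axis); the through-plane
direction is handled by the initial interpolation plus the cross-slice
training-patch collection.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize

from .features import SliceIndex
from .regression import DEFAULT_RIDGE, _solve_pixelwise, required_equations
from .volume import Volume3D

__all__ = [
    "UpsampleParams",
    "ScaleSpaces",
    "build_scale_spaces",
    "mean_correction",
    "baseline_upsample",
    "upsample_volume",
]

logger = logging.getLogger(__name__)


@dataclass
class UpsampleParams:
    """Algorithm knobs.

    v : search-window radius around the mapped center (default 11).
    r : patch radius; patches are (2r+1) x (2r+1) (default 2).
    p_slices : neighbouring-slice count for training patches, odd (default 5).
    J : similar patches taken per slice (default 11).
    stride : patch-center step on the HR lattice; 1 = dense overlap.  Any
        stride <= 2r+1 still covers every voxel (lattice endpoints are
        always included).
    ridge : relative Tikhonov fraction for the per-pixel solves.
    ridge_floor : absolute Tikhonov floor (on [0,1]-normalized
        intensities); shrinks derivative estimates toward the zeroth-order
        patch copy wherever the training offsets are too small to
        determine them.
    zoom : per-axis integer upsampling factors, axis 0 = slice axis.
    seed : recorded for provenance; the reconstruction itself is
        deterministic.
    """

    v: int = 11
    r: int = 2
    p_slices: int = 5
    J: int = 11
    stride: int = 1
    ridge: float = DEFAULT_RIDGE
    ridge_floor: float = 1e-3
    zoom: tuple[int, int, int] = (2, 2, 2)
    seed: int = 0
    prefilter_sigma: float = 0.0

    def __post_init__(self) -> None:
        if not (self.v >= self.r >= 1):
            raise ValueError(f"need v >= r >= 1, got v={self.v}, r={self.r}")
        if self.p_slices < 1 or self.p_slices % 2 == 0:
            raise ValueError(f"p_slices must be odd >= 1, got {self.p_slices}")
        if self.J < 1:
            raise ValueError(f"J must be >= 1, got {self.J}")
        if self.stride < 1:
            raise ValueError(f"stride must be >= 1, got {self.stride}")
        if self.ridge < 0 or self.ridge_floor < 0:
            raise ValueError("ridge terms must be >= 0")
        z = tuple(int(f) for f in self.zoom)
        if len(z) != 3 or any(f < 1 for f in z) or tuple(self.zoom) != z:
            raise ValueError(f"zoom must be 3 integers >= 1, got {self.zoom}")
        self.zoom = z
        need = required_equations(self.r)
        have = self.p_slices * self.J
        if have <= need:
            logger.warning(
                "p_slices*J = %d does not exceed the %d unknown coefficients; "
                "the decoupled solver still only needs >= 2 distinct offsets "
                "per pixel, but the fit may be under-determined",
                have,
                need,
            )


@dataclass
class ScaleSpaces:
    """The query grid Z_s (HR shape) and training image I_s (LR shape)."""

    Z_s: Volume3D
    I_s: Volume3D
    zoom: tuple[int, int, int] = field(default=(2, 2, 2))


def _resize(data: np.ndarray, shape, order: int) -> np.ndarray:
    return resize(
        data,
        shape,
        order=order,
        mode="symmetric",
        anti_aliasing=False,
        preserve_range=True,
        clip=False,
    )


def build_scale_spaces(I: Volume3D, zoom: tuple[int, int, int]) -> ScaleSpaces:
    """Construct Z_s (bicubic upscaling) and I_s (bilinear down/up blur).

    Z_s interpolates I onto the zoomed grid with cubic splines (voxel
    centers aligned); I_s is I bilinearly downsampled by the same factors
    and bilinearly upsampled back to I's grid, i.e. a resampling blur that
    mimics the LR acquisition one scale further down.
    """
    zoom = tuple(int(f) for f in zoom)
    if any(f < 1 for f in zoom):
        raise ValueError(f"zoom factors must be >= 1, got {zoom}")
    shape = I.data.shape
    if any(f > 1 and n < 4 for n, f in zip(shape, zoom)):
        raise ValueError(f"axes {shape} too small for cubic interpolation stencils")
    hr_shape = tuple(n * f for n, f in zip(shape, zoom))
    hr_voxel = tuple(vs / f for vs, f in zip(I.voxel_size, zoom))

    if all(f == 1 for f in zoom):
        Zs_data = I.data.copy()
    else:
        Zs_data = _resize(I.data, hr_shape, order=3)

    small = tuple(max(1, round(n / f)) for n, f in zip(shape, zoom))
    if small == shape:
        Is_data = I.data.copy()
    else:
        Is_data = _resize(_resize(I.data, small, order=1), shape, order=1)

    return ScaleSpaces(
        Z_s=Volume3D(np.maximum(Zs_data, 0.0), voxel_size=hr_voxel),
        I_s=Volume3D(np.maximum(Is_data, 0.0), voxel_size=I.voxel_size),
        zoom=zoom,
    )


def mean_correction(Z: Volume3D, I: Volume3D, zoom: tuple[int, int, int]) -> Volume3D:
    """Shift every zoom-block of Z so its mean equals the LR voxel of I.

    Enforces consistency with the block-averaging acquisition model: after
    correction, ``block_downsample(Z, zoom) == I`` exactly (within float
    round-off).
    """
    zoom = tuple(int(f) for f in zoom)
    f0, f1, f2 = zoom
    n0, n1, n2 = I.data.shape
    if Z.data.shape != (n0 * f0, n1 * f1, n2 * f2):
        raise ValueError(
            f"HR shape {Z.data.shape} is not LR shape {I.data.shape} x zoom {zoom}"
        )
    blocks = Z.data.reshape(n0, f0, n1, f1, n2, f2)
    block_mean = blocks.mean(axis=(1, 3, 5))
    shift = (I.data - block_mean)[:, None, :, None, :, None]
    corrected = (blocks + shift).reshape(Z.data.shape)
    return Z.copy_with(corrected)


def baseline_upsample(I: Volume3D, zoom: tuple[int, int, int], order: int = 1) -> Volume3D:
    """Plain interpolation baseline (order 1 = trilinear, 0 = nearest)."""
    zoom = tuple(int(f) for f in zoom)
    hr_shape = tuple(n * f for n, f in zip(I.data.shape, zoom))
    data = _resize(I.data, hr_shape, order=order)
    vs = tuple(v / f for v, f in zip(I.voxel_size, zoom))
    return Volume3D(np.maximum(data, 0.0), voxel_size=vs)


def _center_lattice(n: int, stride: int) -> np.ndarray:
    """Stride lattice over [0, n), always including the last index."""
    pts = list(range(0, n, stride))
    if pts[-1] != n - 1:
        pts.append(n - 1)
    return np.asarray(pts)


def upsample_volume(I: Volume3D, params: UpsampleParams) -> Volume3D:
    """Reconstruct the HR volume Z from the LR input I (assumed denoised).

    Intensities are min-max normalized to [0, 1] internally (so the
    descriptor and ridge constants are scale-free) and restored afterwards.
    Deterministic: identical inputs and parameters give identical output.
    """
    zoom = params.zoom
    r, v, J, stride = params.r, params.v, params.J, params.stride
    s = 2 * r + 1
    n_lr = I.data.shape
    hr_shape = tuple(n * f for n, f in zip(n_lr, zoom))
    hr_voxel = tuple(vs / f for vs, f in zip(I.voxel_size, zoom))
    if any(n < s for n in n_lr[1:]):
        raise ValueError(f"in-plane LR size {n_lr[1:]} smaller than patch size {s}")

    lo, hi = I.intensity_range
    if hi <= lo:
        # flat volume: the mapping is the identity on its only intensity
        return Volume3D(np.full(hr_shape, lo), voxel_size=hr_voxel)
    x = (I.data - lo) / (hi - lo)

    if params.prefilter_sigma > 0:
        from .degrade import gaussian_blur_3d

        x = gaussian_blur_3d(Volume3D(x), params.prefilter_sigma).data

    spaces = build_scale_spaces(Volume3D(x, voxel_size=I.voxel_size), zoom)
    Zs = spaces.Z_s.data
    Is = spaces.I_s.data

    # per-LR-slice indexes: descriptors/patches of I_s, patch windows of I
    lr_index = [SliceIndex(Is[z], r) for z in range(n_lr[0])]
    hr_windows = [
        sliding_window_view(np.pad(x[z], r, mode="reflect"), (s, s))
        for z in range(n_lr[0])
    ]

    acc = np.zeros((hr_shape[0], hr_shape[1] + 2 * r, hr_shape[2] + 2 * r))
    cnt = np.zeros_like(acc)
    rows_lat = _center_lattice(hr_shape[1], stride)
    cols_lat = _center_lattice(hr_shape[2], stride)
    half = params.p_slices // 2
    n = s * s

    t0 = time.perf_counter()
    for z in range(hr_shape[0]):
        zl = min(n_lr[0] - 1, int(round(z / zoom[0])))
        z_lo, z_hi = max(0, zl - half), min(n_lr[0], zl + half + 1)
        q_index = SliceIndex(Zs[z], r)
        for row in rows_lat:
            lr_row = min(n_lr[1] - 1, int(round(row / zoom[1])))
            for col in cols_lat:
                lr_col = min(n_lr[2] - 1, int(round(col / zoom[2])))
                q_cov = q_index.covs[row, col]
                qs_vec = q_index.patches[row, col].ravel()

                (pr, pc), _ = lr_index[zl].best_in_window((lr_row, lr_col), v, q_cov)
                ps_vec = lr_index[zl].patches[pr, pc].ravel()
                p_vec = hr_windows[zl][pr, pc].ravel()
                ps_cov = lr_index[zl].covs[pr, pc]

                stacks_lr, stacks_hr, stacks_w = [], [], []
                for zt in range(z_lo, z_hi):
                    trows, tcols, tw = lr_index[zt].topj_in_window(
                        (pr, pc), v, J, ps_cov
                    )
                    stacks_lr.append(
                        lr_index[zt].patches[trows, tcols].reshape(-1, n)
                    )
                    stacks_hr.append(hr_windows[zt][trows, tcols].reshape(-1, n))
                    stacks_w.append(tw)
                lr_stack = np.concatenate(stacks_lr)
                hr_stack = np.concatenate(stacks_hr)
                weights = np.concatenate(stacks_w)

                f1, f2 = _solve_pixelwise(
                    lr_stack - ps_vec,
                    hr_stack - p_vec,
                    weights,
                    params.ridge,
                    params.ridge_floor,
                )
                d = qs_vec - ps_vec
                qhat = p_vec + f1 * d + 0.5 * f2 * d * d

                acc[z, row : row + s, col : col + s] += qhat.reshape(s, s)
                cnt[z, row : row + s, col : col + s] += 1.0
        if z % 16 == 0 or z == hr_shape[0] - 1:
            logger.info(
                "slice %d/%d reconstructed (%.1fs elapsed)",
                z + 1,
                hr_shape[0],
                time.perf_counter() - t0,
            )

    core_acc = acc[:, r : r + hr_shape[1], r : r + hr_shape[2]]
    core_cnt = cnt[:, r : r + hr_shape[1], r : r + hr_shape[2]]
    covered = core_cnt > 0
    Z = np.where(covered, core_acc / np.maximum(core_cnt, 1.0), Zs)

    # clamp to the normalized intensity range before mean correction: a
    # Taylor extrapolation cannot be trusted outside the observed range
    Z = np.clip(Z, 0.0, 1.0)
    # no clipping after this point: mean correction's block-mean identity
    # with the LR input is the pipeline's consistency guarantee
    Z = mean_correction(Volume3D(Z), Volume3D(x), zoom).data
    Z = Z * (hi - lo) + lo
    return Volume3D(Z, voxel_size=hr_voxel)
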