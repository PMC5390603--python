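"""Volume quality metrics: PSNR, SSIM, mutual information.

PSNR is reported in decibels against the reference volume's dynamic range;
SSIM uses the standard 11x11 Gaussian window (sigma 1.5, K1=0.01,
K2=0.03), computed per axial slice and averaged; mutual information is
estimated in bits from a joint histogram with equal-width bins spanning
each volume's own range (64 bins by default), so it is invariant to affine
intensity rescaling of either volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

from .volume import Volume3D

__all__ = ["MetricsReport", "psnr", "ssim", "mutual_information", "evaluate"]


@dataclass
class MetricsReport:
    """The three scores plus the estimator conventions that produced them."""

    psnr: float
    ssim: float
    mi: float
    params: dict = field(default_factory=dict)

    def as_line(self) -> str:
        return f"{self.psnr:.4f}\t{self.ssim:.6f}\t{self.mi:.6f}"


def _data(vol) -> np.ndarray:
    return vol.data if isinstance(vol, Volume3D) else np.asarray(vol, dtype=np.float64)


def _check_shapes(ref: np.ndarray, test: np.ndarray) -> None:
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")


def psnr(ref, test) -> float:
    """Peak signal-to-noise ratio, dB: ``10 log10(R^2 / MSE)``.

    R is the reference's dynamic range (max - min).  Identical volumes
    return ``inf``.
    """
    ref, test = _data(ref), _data(test)
    _check_shapes(ref, test)
    R = ref.max() - ref.min()
    if R <= 0:
        raise ValueError("reference volume has no dynamic range")
    mse = np.mean((ref - test) ** 2)
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(R * R / mse))


def ssim(ref, test) -> float:
    """Mean structural similarity, computed per axial slice and averaged.

    Gaussian-weighted 11x11 windows, sigma=1.5, K1=0.01, K2=0.03, dynamic
    range taken from the reference volume.  In-plane axes must be >= 11.
    """
    ref, test = _data(ref), _data(test)
    _check_shapes(ref, test)
    if ref.shape[1] < 11 or ref.shape[2] < 11:
        raise ValueError(f"in-plane axes must be >= 11 for SSIM, got {ref.shape[1:]}")
    R = ref.max() - ref.min()
    if R <= 0:
        R = 1.0  # two constant volumes: stabilizing constants decide
    vals = [
        structural_similarity(
            ref[z],
            test[z],
            win_size=11,
            gaussian_weights=True,
            sigma=1.5,
            K1=0.01,
            K2=0.03,
            use_sample_covariance=False,
            data_range=R,
        )
        for z in range(ref.shape[0])
    ]
    return float(np.mean(vals))


def mutual_information(ref, test, bins: int = 64) -> float:
    """Mutual information in bits from a ``bins x bins`` joint histogram.

    Each volume is binned with equal-width bins spanning its own range;
    empty joint bins contribute zero.
    """
    ref, test = _data(ref), _data(test)
    _check_shapes(ref, test)
    if bins < 2:
        raise ValueError(f"need at least 2 bins, got {bins}")
    joint, _, _ = np.histogram2d(ref.ravel(), test.ravel(), bins=bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    outer = px[:, None] * py[None, :]
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log2(pxy[nz] / outer[nz])))


def evaluate(ref, test, bins: int = 64) -> MetricsReport:
    """All three metrics in one report, with the conventions recorded."""
    return MetricsReport(
        psnr=psnr(ref, test),
        ssim=ssim(ref, test),
        mi=mutual_information(ref, test, bins=bins),
        params={
            "ssim_window": 11,
            "ssim_sigma": 1.5,
            "ssim_mode": "2d-per-slice-averaged",
            "mi_bins": bins,
            "mi_log_base": 2,
            "mi_binning": "per-volume equal-width",
            "psnr_range": "reference max-min",
        },
    )
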