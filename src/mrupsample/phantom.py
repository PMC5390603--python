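"""Brain-like synthetic phantoms.

Real T1-weighted brain volumes owe their cross-scale patch self-similarity
to three ingredients: laminar/shell anatomy (cortical ribbon, ventricle
walls), smooth intensity gradations (bias-field-like slow variation and
partial-volume ramps) and fine stochastic texture (white-matter striation,
noise-free tissue micro-contrast).  The phantom combines all three —
nested ellipsoidal shells, a smooth intensity ramp and a band-limited
random texture — so patches recur within and across slices, which is the
working assumption of every patch-search stage downstream.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volume import Volume3D

__all__ = ["make_phantom"]

_MIN_AXIS = 16


def make_phantom(shape: tuple[int, int, int], seed: int) -> Volume3D:
    """Deterministic brain-like test volume with intensities in [0, 1].

    Parameters
    ----------
    shape : tuple of int
        Axis lengths, each at least 16.
    seed : int
        Seeds the band-limited texture component; identical seeds give
        bit-identical volumes.

    Returns
    -------
    Volume3D
        Nested ellipsoidal shells of alternating contrast, overlaid with a
        smooth linear ramp and a low-pass-filtered noise texture, rescaled
        to span [0, 1].
    """
    shape = tuple(int(n) for n in shape)
    if len(shape) != 3:
        raise ValueError(f"shape must have 3 axes, got {shape}")
    if any(n < _MIN_AXIS for n in shape):
        raise ValueError(f"each axis must be >= {_MIN_AXIS}, got {shape}")

    rng = np.random.default_rng(seed)
    grids = np.meshgrid(
        *[np.linspace(-1.0, 1.0, n) for n in shape], indexing="ij", sparse=True
    )

    # Nested shells: alternating-intensity concentric ellipsoid layers,
    # mildly anisotropic so axial slices show laminar curved bands.
    rho = np.sqrt(grids[0] ** 2 + (1.15 * grids[1]) ** 2 + (0.9 * grids[2]) ** 2)
    shells = 0.5 + 0.5 * np.cos(9.0 * np.pi * rho)
    shells *= rho < 0.92  # skull boundary: zero background outside

    # Smooth ramp: slow linear intensity drift across the volume.
    ramp = 0.5 + 0.25 * grids[1] + 0.15 * grids[2] + 0.1 * grids[0]

    # Band-limited texture: white noise low-passed to ~2-voxel grain, so it
    # survives mild blurring and recurs statistically across nearby slices.
    texture = ndimage.gaussian_filter(
        rng.standard_normal(shape), sigma=1.5, mode="mirror"
    )
    texture /= max(np.abs(texture).max(), np.finfo(float).tiny)

    vol = 0.55 * shells + 0.3 * ramp + 0.15 * (0.5 + 0.5 * texture)
    vol -= vol.min()
    vol /= vol.max()
    return Volume3D(vol)
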