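"""The 3-D volume carrier and NIfTI round-trip helpers.

A :class:`Volume3D` is a thin wrapper around a 3-D floating-point intensity
array together with physical voxel sizes (mm per axis).  It is the common
currency of the whole pipeline: high-resolution ground truth, acquired
low-resolution input, scale-space images and reconstructions are all
Volume3D instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import nibabel as nib

__all__ = ["Volume3D", "load_volume", "save_volume"]


@dataclass
class Volume3D:
    """A 3-D scalar intensity grid with voxel-size metadata.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Nonnegative, finite intensities.  Axis 0 is treated as the
        slice-selection (through-plane) axis throughout the package.
    voxel_size : tuple of float
        Physical edge length of a voxel along each axis, in mm.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        if any(n < 1 for n in self.data.shape):
            raise ValueError(f"all axis lengths must be >= 1, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be 3 strictly positive values, got {vs}")
        self.voxel_size = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def intensity_range(self) -> tuple[float, float]:
        return float(self.data.min()), float(self.data.max())

    def copy_with(self, data: np.ndarray, voxel_size=None) -> "Volume3D":
        """A new volume carrying ``data``, inheriting metadata unless overridden."""
        return Volume3D(
            data,
            voxel_size=self.voxel_size if voxel_size is None else voxel_size,
            affine=None if self.affine is None else self.affine.copy(),
        )


def load_volume(path) -> Volume3D:
    """Read a NIfTI-1 volume (.nii / .nii.gz)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    zooms = img.header.get_zooms()[:3]
    return Volume3D(data, voxel_size=tuple(float(z) for z in zooms), affine=img.affine)


def save_volume(vol: Volume3D, path) -> None:
    """Write a NIfTI-1 volume, preserving the affine when one is attached.

    Without a stored affine a diagonal affine is synthesised from the voxel
    size so that downstream viewers see correct physical spacing.
    """
    if vol.affine is not None:
        affine = vol.affine
    else:
        affine = np.diag(list(vol.voxel_size) + [1.0])
    img = nib.Nifti1Image(vol.data, affine)
    img.header.set_zooms(vol.voxel_size)
    nib.save(img, str(path))
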