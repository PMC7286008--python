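"""Voxel volumes and NIfTI I/O.

All volumes in this package use axis order ``(z, y, x)`` with 0-based voxel
indices and per-axis spacing in millimetres.  A volume carries either CT-style
intensities in Hounsfield units (HU) or nonnegative MRI intensities in
arbitrary units; which one is a matter of convention at the call site, the
container does not distinguish them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import nibabel as nib

__all__ = ["ImageVolume", "read_volume", "write_volume"]


@dataclass
class ImageVolume:
    """A voxel grid with physical spacing.

    Parameters
    ----------
    data : ndarray
        Voxel values, axis order (z, y, x).
    spacing : tuple of float
        Voxel size in mm per axis, same order as ``data`` axes.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D (z, y, x), got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive mm values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.data.copy(), self.spacing)

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        """Same grid, new voxel values."""
        if data.shape != self.data.shape:
            raise ValueError(f"shape mismatch: {data.shape} vs {self.data.shape}")
        return ImageVolume(data, self.spacing)


def read_volume(path) -> ImageVolume:
    """Read a NIfTI file into an :class:`ImageVolume`.

    The on-disk array is stored nibabel-style as (x, y, z); it is transposed to
    this package's (z, y, x) convention on read.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - error path message
        raise IOError(f"could not read volume from {path!s}: {exc}") from exc
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 3:
        raise IOError(f"{path!s}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]  # (x, y, z)
    return ImageVolume(np.transpose(data, (2, 1, 0)), spacing=(zooms[2], zooms[1], zooms[0]))


def write_volume(vol: ImageVolume, path) -> None:
    """Write an :class:`ImageVolume` as NIfTI (.nii or .nii.gz)."""
    sx, sy, sz = vol.spacing[2], vol.spacing[1], vol.spacing[0]
    affine = np.diag([sx, sy, sz, 1.0])
    data = np.transpose(vol.data.astype(np.float32), (2, 1, 0))
    nib.save(nib.Nifti1Image(data, affine), str(path))
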