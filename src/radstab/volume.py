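"""3D image volumes with physical-space metadata.

Arrays are indexed ``[z, y, x]`` (slowest axis first, the NumPy convention
used by SimpleITK's array views); ``spacing`` and ``origin`` follow the same
``(z, y, x)`` order and are expressed in millimeters.  World coordinate of
grid index ``(i, j, k)`` is ``origin + index * spacing`` per axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

__all__ = ["ImageVolume", "read_nrrd", "write_nrrd"]


@dataclass
class ImageVolume:
    """A 3D scalar grid with isotropic-or-not voxel spacing.

    Parameters
    ----------
    values
        3D array, indexed ``[z, y, x]``.  Finite values only.
    spacing
        Voxel size in mm per axis, ``(z, y, x)`` order, all > 0.
    origin
        World position of voxel ``(0, 0, 0)`` in mm, ``(z, y, x)`` order.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if np.issubdtype(self.values.dtype, np.floating) and not np.all(
            np.isfinite(self.values)
        ):
            raise ValueError("values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.values))
        img.SetSpacing(tuple(reversed(self.spacing)))  # sitk wants (x, y, z)
        img.SetOrigin(tuple(reversed(self.origin)))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "ImageVolume":
        return cls(
            values=sitk.GetArrayFromImage(img),
            spacing=tuple(reversed(img.GetSpacing())),
            origin=tuple(reversed(img.GetOrigin())),
        )


def binarize(mask: ImageVolume) -> ImageVolume:
    """Return a {0,1} uint8 copy of a mask volume."""
    return ImageVolume(
        (np.asarray(mask.values) > 0.5).astype(np.uint8), mask.spacing, mask.origin
    )


def check_mask(volume: ImageVolume, mask: ImageVolume) -> np.ndarray:
    """Validate that mask aligns with volume; return the boolean foreground."""
    if mask.values.shape != volume.values.shape:
        raise ValueError(
            f"mask shape {mask.values.shape} != volume shape {volume.values.shape}"
        )
    if not np.allclose(mask.spacing, volume.spacing):
        raise ValueError(f"mask spacing {mask.spacing} != volume spacing {volume.spacing}")
    fg = np.asarray(mask.values) > 0.5
    if not fg.any():
        raise ValueError("mask has no foreground voxels")
    return fg


def write_nrrd(volume: ImageVolume, path) -> None:
    """Write a volume (or mask) to NRRD, carrying spacing and origin."""
    sitk.WriteImage(volume.to_sitk(), str(path), useCompression=False)


def read_nrrd(path) -> ImageVolume:
    """Read an NRRD file into an :class:`ImageVolume`."""
    return ImageVolume.from_sitk(sitk.ReadImage(str(path)))
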