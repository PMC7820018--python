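"""Resampling, threshold segmentation and gray-level discretization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from ..volume import ImageVolume, check_mask

__all__ = ["DiscretizedRoi", "resample_isotropic", "threshold_segment", "discretize"]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def resample_isotropic(
    volume: ImageVolume, mask: ImageVolume, target: float = 2.0
) -> tuple[ImageVolume, ImageVolume]:
    """Resample volume + mask to isotropic ``target`` mm voxels.

    Intensities use cubic B-spline interpolation; the mask uses
    nearest-neighbor and is re-binarized.  The physical extent is
    preserved to within one voxel (output size = round(extent / target)).
    """
    if target <= 0:
        raise ValueError(f"target spacing must be > 0, got {target}")
    check_mask(volume, mask)
    img = volume.to_sitk()
    msk = sitk.Cast(mask.to_sitk(), sitk.sitkUInt8)
    old_size = np.array(img.GetSize(), dtype=float)  # (x, y, z)
    old_spacing = np.array(img.GetSpacing(), dtype=float)
    new_size = np.maximum(np.round(old_size * old_spacing / target), 1).astype(int)

    def _resample(image, interp):
        res = sitk.ResampleImageFilter()
        res.SetOutputSpacing((target, target, target))
        res.SetSize([int(s) for s in new_size])
        res.SetOutputOrigin(image.GetOrigin())
        res.SetOutputDirection(image.GetDirection())
        res.SetInterpolator(interp)
        res.SetDefaultPixelValue(0)
        return res.Execute(image)

    out_img = ImageVolume.from_sitk(_resample(img, sitk.sitkBSpline))
    out_msk = ImageVolume.from_sitk(_resample(msk, sitk.sitkNearestNeighbor))
    out_msk.values = (out_msk.values > 0.5).astype(np.uint8)
    if not out_msk.values.any():
        raise ValueError("ROI is empty after resampling (degenerate mask)")
    return out_img, out_msk


def threshold_segment(volume: ImageVolume, fraction: float = 0.40) -> ImageVolume:
    """Threshold at ``fraction`` of the global maximum; keep largest blob.

    Voxels with intensity >= fraction x max form the candidate set; the
    largest 26-connected component is returned as a {0,1} mask.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    v = volume.values
    thr = fraction * float(v.max())
    candidate = v >= thr
    if not candidate.any():
        raise ValueError("threshold segmentation produced an empty mask")
    labels, n = ndimage.label(candidate, structure=_STRUCT_26)
    if n == 0:
        raise ValueError("threshold segmentation produced an empty mask")
    counts = np.bincount(labels.ravel())[1:]
    biggest = int(np.argmax(counts)) + 1
    return ImageVolume((labels == biggest).astype(np.uint8), volume.spacing, volume.origin)


@dataclass
class DiscretizedRoi:
    """Gray levels of the in-mask voxels after fixed-bin-width binning.

    ``labels`` is the full grid with levels 1..n_levels inside the mask and
    0 outside; ``levels_flat`` the in-mask levels in C order.  Level of
    voxel v = floor((I(v) - min_in_mask) / bin_width) + 1, anchoring the
    binning at the in-ROI minimum (hence shift-invariant).
    """

    labels: np.ndarray
    n_levels: int
    bin_width: float
    mask: np.ndarray

    @property
    def levels_flat(self) -> np.ndarray:
        return self.labels[self.mask]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def histogram(self) -> np.ndarray:
        """Counts per level 1..n_levels."""
        return np.bincount(self.levels_flat, minlength=self.n_levels + 1)[1:]


def discretize(volume: ImageVolume, mask: ImageVolume, bin_width: float = 25.0) -> DiscretizedRoi:
    """Fixed-bin-width gray-level discretization of the in-mask intensities."""
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    fg = check_mask(volume, mask)
    vals = volume.values[fg].astype(float)
    lo = vals.min()
    levels = np.floor((volume.values - lo) / bin_width).astype(np.int64) + 1
    labels = np.where(fg, levels, 0)
    n_levels = int(labels.max())
    return DiscretizedRoi(labels=labels, n_levels=n_levels, bin_width=float(bin_width), mask=fg)
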