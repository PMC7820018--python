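"""Laplacian-of-Gaussian and undecimated 3D wavelet filtering.

Both filters operate on the image grid and return volumes on the same
grid, so the same ROI mask applies to every filtered image.
"""

from __future__ import annotations

import logging

import numpy as np
import pywt
from scipy import ndimage

from ..volume import ImageVolume

logger = logging.getLogger(__name__)

__all__ = ["log_filter", "wavelet_decompose", "WAVELET_SUBBANDS"]

#: Sub-band labels; letter i is the filter (L = low pass, H = high pass)
#: applied along array axis i.
WAVELET_SUBBANDS = ["LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH"]


def log_filter(volume: ImageVolume, sigma: float) -> ImageVolume:
    """Scale-normalized Laplacian-of-Gaussian response at ``sigma`` (mm).

    The Gaussian scale is converted to voxels per axis via the spacing and
    the second derivatives are taken in physical units (per mm^2), then
    multiplied by sigma^2 (gamma-normalization), the convention of the
    standard radiomics toolchains: it keeps the response amplitude — and
    hence the fixed-bin-width discretization — comparable across scales.
    A sigma under half the smallest voxel dimension is under-resolved: a
    warning is logged but the filter is still applied.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if sigma < min(volume.spacing) / 2.0:
        logger.warning(
            "LoG sigma %.3g mm is under-resolved for voxel spacing %s", sigma, volume.spacing
        )
    vals = volume.values.astype(float)
    kernels = [_gauss_kernels(sigma / sp) for sp in volume.spacing]
    out = np.zeros_like(vals)
    for axis, sp in enumerate(volume.spacing):
        resp = vals
        for ax2 in range(3):
            k0, k2 = kernels[ax2]
            resp = ndimage.correlate1d(resp, k2 if ax2 == axis else k0, axis=ax2, mode="reflect")
        out += resp / sp**2
    out *= sigma**2
    return ImageVolume(out, volume.spacing, volume.origin)


def _gauss_kernels(sigma_vox: float, truncate: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
    """Sampled Gaussian and second-derivative kernels for one axis.

    The derivative kernel is projected to exact zero DC gain (the sampled
    second derivative does not sum to zero by itself), so a constant image
    has an exactly zero Laplacian response.
    """
    r = max(1, int(truncate * sigma_vox + 0.5))
    x = np.arange(-r, r + 1, dtype=float)
    g0 = np.exp(-(x**2) / (2.0 * sigma_vox**2))
    g0 /= g0.sum()
    g2 = (x**2 - sigma_vox**2) / sigma_vox**4 * g0
    g2 -= g2.sum() * g0
    return g0, g2


def _subband_kernel(wavelet: str, label: str) -> np.ndarray:
    """Separable 3D kernel of one sub-band (outer product of 1D filters)."""
    w = pywt.Wavelet(wavelet)
    lo, hi = np.asarray(w.dec_lo), np.asarray(w.dec_hi)
    taps = [lo if c == "L" else hi for c in label]
    return taps[0][:, None, None] * taps[1][None, :, None] * taps[2][None, None, :]


def wavelet_decompose(
    volume: ImageVolume, wavelet: str = "coif1"
) -> dict[str, ImageVolume]:
    """Single-level undecimated separable 3D wavelet decomposition.

    Returns all 8 sub-bands (LLL..HHH) on the original grid.  Filtering is
    circular (periodic boundary), matching the stationary-transform
    convention; the filters are the decomposition pair of ``wavelet``
    (Coiflet-1 by default).
    """
    w = pywt.Wavelet(wavelet)
    lo, hi = np.asarray(w.dec_lo), np.asarray(w.dec_hi)
    if min(volume.shape) < len(lo):
        raise ValueError(
            f"volume shape {volume.shape} smaller than the {len(lo)}-tap "
            f"{wavelet} filter support"
        )
    vals = volume.values.astype(float)
    # low/high-pass along each axis once, then combine
    partial = {"": vals}
    for axis in range(3):
        nxt = {}
        for label, arr in partial.items():
            nxt[label + "L"] = ndimage.convolve1d(arr, lo, axis=axis, mode="wrap")
            nxt[label + "H"] = ndimage.convolve1d(arr, hi, axis=axis, mode="wrap")
        partial = nxt
    return {
        label: ImageVolume(partial[label], volume.spacing, volume.origin)
        for label in WAVELET_SUBBANDS
    }
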