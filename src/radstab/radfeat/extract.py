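"""Full 1080-feature extraction from a volume + mask pair.

Pipeline: resample to isotropic 2 mm -> build the 12 image channels
(original, LoG at sigma 1/2/3 mm, 8 wavelet sub-bands) -> discretize each
channel independently at fixed bin width 25 -> run the six feature-class
extractors (17 + 22 + 16 + 16 + 5 + 14 = 90 features per channel).

Feature ids are ``<filter>_<class>_<Name>``, e.g.
``log-sigma-2-0-mm-3D_glrlm_RunLengthNonUniformity`` or
``wavelet-LLH_glcm_JointEnergy``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ..volume import ImageVolume
from .filters import WAVELET_SUBBANDS, log_filter, wavelet_decompose
from .firstorder import FIRSTORDER_NAMES, firstorder_features
from .preprocess import discretize, resample_isotropic
from .texture import (
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = ["ExtractionConfig", "extract_all", "feature_roster", "EXPECTED_FEATURE_COUNT"]

CLASS_NAMES = {
    "firstorder": FIRSTORDER_NAMES,
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "ngtdm": NGTDM_NAMES,
    "gldm": GLDM_NAMES,
}

EXPECTED_FEATURE_COUNT = 1080  # 90 features x (1 original + 3 LoG + 8 wavelet)


def _sigma_label(sigma: float) -> str:
    return "log-sigma-" + f"{sigma:.1f}".replace(".", "-") + "-mm-3D"


@dataclass
class ExtractionConfig:
    """Extraction settings; the defaults are the study protocol.

    ``resample_mm=None`` skips resampling (used by locality tests and when
    the input grid is already the analysis grid).
    """

    bin_width: float = 25.0
    resample_mm: float | None = 2.0
    log_sigmas_mm: tuple[float, ...] = (1.0, 2.0, 3.0)
    wavelet: str = "coif1"
    enable_log: bool = True
    enable_wavelet: bool = True

    def filter_labels(self) -> list[str]:
        labels = ["original"]
        if self.enable_log:
            labels += [_sigma_label(s) for s in self.log_sigmas_mm]
        if self.enable_wavelet:
            labels += [f"wavelet-{b}" for b in WAVELET_SUBBANDS]
        return labels


def feature_roster(config: ExtractionConfig | None = None) -> list[str]:
    """Canonical ordered list of feature ids for a configuration."""
    config = config or ExtractionConfig()
    return [
        f"{filt}_{cls}_{name}"
        for filt in config.filter_labels()
        for cls, names in CLASS_NAMES.items()
        for name in names
    ]


def extract_all(
    volume: ImageVolume, mask: ImageVolume, config: ExtractionConfig | None = None
) -> dict[str, float]:
    """Extract every enabled feature; returns an ordered id -> value map."""
    config = config or ExtractionConfig()
    if config.resample_mm is not None:
        volume, mask = resample_isotropic(volume, mask, config.resample_mm)

    channels: dict[str, ImageVolume] = {"original": volume}
    if config.enable_log:
        for s in config.log_sigmas_mm:
            channels[_sigma_label(s)] = log_filter(volume, s)
    if config.enable_wavelet:
        for band, img in wavelet_decompose(volume, config.wavelet).items():
            channels[f"wavelet-{band}"] = img

    out: dict[str, float] = {}
    for filt, img in channels.items():
        try:
            droi = discretize(img, mask, config.bin_width)
            per_class = {
                "firstorder": firstorder_features(img, mask, config.bin_width, droi),
                "glcm": glcm_features(droi),
                "glrlm": glrlm_features(droi),
                "glszm": glszm_features(droi),
                "ngtdm": ngtdm_features(droi),
                "gldm": gldm_features(droi),
            }
        except Exception as exc:  # re-raise with channel context attached
            raise RuntimeError(f"feature extraction failed in channel {filt!r}") from exc
        for cls, names in CLASS_NAMES.items():
            vals = per_class[cls]
            for name in names:
                out[f"{filt}_{cls}_{name}"] = vals[name]
    return out
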