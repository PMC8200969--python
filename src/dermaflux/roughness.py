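"""Fine-surface roughness from the spatial spectrum of relative shadows.

Slow illumination and face-shape shading are divided out first
(``s = lum / G(sigma_illum)*lum - 1``); the score is 100x the RMS of the
relative-shadow map restricted to a radial frequency band, which makes it
invariant to global brightness and insensitive to out-of-band shading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from ._spectral import bandpass_rms, validate_band
from .core_io import ROI, ROILabel, SkinImage, extract_roi
from .pores import luminance

__all__ = ["RoughnessResult", "relative_shadow_map", "roughness_score"]

DEFAULT_BAND = (0.02, 0.15)  # cycles/px at ~10 px/mm
DEFAULT_SIGMA_ILLUM = 30.0  # px
AU_SCALE = 100.0

#: Luminance floor guarding the division in the shadow normalization.
LUM_FLOOR = 1e-4


@dataclass(frozen=True)
class RoughnessResult:
    roughness_au: float
    band_cycles_per_px: tuple[float, float]
    roi_area_px: int


def relative_shadow_map(lum: np.ndarray, sigma_illum: float = DEFAULT_SIGMA_ILLUM) -> np.ndarray:
    """Illumination-normalized local shading: ``lum / G(sigma)*lum - 1``.

    Scale-invariant (a global gain cancels in the ratio) and near zero-mean
    on large rasters.
    """
    lum = np.maximum(np.asarray(lum, dtype=np.float64), LUM_FLOOR)
    base = gaussian_filter(lum, sigma_illum, mode="nearest")
    return lum / base - 1.0


def roughness_score(
    img: SkinImage,
    roi: ROI,
    band: tuple[float, float] = DEFAULT_BAND,
    sigma_illum: float = DEFAULT_SIGMA_ILLUM,
) -> RoughnessResult:
    """Band-limited RMS of the relative-shadow map over the eye-to-cheek ROI."""
    validate_band(band)
    if img.color_state != "calibrated":
        raise ValueError("roughness_score requires a calibrated image")
    if roi.label is not ROILabel.EYE_TO_CHEEK:
        raise ValueError(f"roughness_score expects an eye_to_cheek ROI, got {roi.label.value}")
    patch = extract_roi(img, roi)
    s = relative_shadow_map(luminance(patch.pixels), sigma_illum)
    return RoughnessResult(
        roughness_au=AU_SCALE * bandpass_rms(s, band),
        band_cycles_per_px=(float(band[0]), float(band[1])),
        roi_area_px=roi.area_px,
    )
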