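"""Cheek redness from a hemoglobin-tone map.

Hemoglobin absorbs green preferentially, so the per-pixel index is the
optical-density-style contrast ``h = log10(R / G)``. The score combines a
brightness component (100x the ROI mean of ``h``) with a variation
component (100x the RMS of ``h`` band-passed at blotch scale), summed with
configurable weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._spectral import bandpass_rms, validate_band
from .core_io import ROI, ROILabel, SkinImage, extract_roi

__all__ = ["RednessResult", "hemoglobin_map", "redness_score"]

#: Erythema varies over mm-cm scales, an order of magnitude below texture.
DEFAULT_BAND = (0.005, 0.05)
AU_SCALE = 100.0
CHANNEL_FLOOR = 1e-4


@dataclass(frozen=True)
class RednessResult:
    redness_au: float
    brightness_component_au: float
    variation_component_au: float
    band_cycles_per_px: tuple[float, float]


def hemoglobin_map(img: SkinImage, roi: ROI) -> np.ndarray:
    """Per-pixel ``log10(R / G)`` over the cheek ROI, channels floored at 1e-4."""
    if roi.label is not ROILabel.CHEEK:
        raise ValueError(f"hemoglobin_map expects a cheek ROI, got {roi.label.value}")
    patch = extract_roi(img, roi).pixels
    r = np.maximum(patch[..., 0], CHANNEL_FLOOR)
    g = np.maximum(patch[..., 1], CHANNEL_FLOOR)
    return np.log10(r / g)


def redness_score(
    img: SkinImage,
    roi: ROI,
    band: tuple[float, float] = DEFAULT_BAND,
    w_brightness: float = 1.0,
    w_variation: float = 1.0,
) -> RednessResult:
    """Brightness + band-limited variation of the hemoglobin map."""
    validate_band(band)
    if img.color_state != "calibrated":
        raise ValueError("redness_score requires a calibrated image")
    h = hemoglobin_map(img, roi)
    brightness = AU_SCALE * float(h.mean())
    variation = AU_SCALE * bandpass_rms(h, band)
    return RednessResult(
        redness_au=w_brightness * brightness + w_variation * variation,
        brightness_component_au=brightness,
        variation_component_au=variation,
        band_cycles_per_px=(float(band[0]), float(band[1])),
    )
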