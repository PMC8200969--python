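"""Gray-tip color calibration.

The capture frame carries a neutral gray reference patch at a fixed,
configured location. Calibration is a per-channel linear gain
(von-Kries style): ``gain_c = nominal_reflectance / mean_c(tip ROI)``.
No offset term and no cross-channel matrix are applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import ROI, ROILabel, SkinImage, extract_roi

__all__ = ["GrayReference", "CalibrationError", "measure_gray", "calibrate"]

#: Flat-patch screen: per-channel coefficient of variation above this value
#: suggests the tip was occluded or unevenly lit.
CV_LIMIT = 0.2

DEFAULT_NOMINAL_REFLECTANCE = 0.5


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class GrayReference:
    """Per-channel mean of the gray-tip ROI plus the tip's known gray level."""

    measured_rgb: tuple[float, float, float]
    nominal_reflectance: float = DEFAULT_NOMINAL_REFLECTANCE
    cv_rgb: tuple[float, float, float] = (0.0, 0.0, 0.0)
    suspect: bool = False

    def __post_init__(self) -> None:
        if any(m <= 0.0 for m in self.measured_rgb):
            raise CalibrationError(
                f"gray reference requires strictly positive channel means, got {self.measured_rgb}"
            )
        if not 0.0 < self.nominal_reflectance < 1.0:
            raise CalibrationError(
                f"nominal_reflectance must be in (0, 1), got {self.nominal_reflectance}"
            )

    @property
    def gains(self) -> tuple[float, float, float]:
        return tuple(self.nominal_reflectance / m for m in self.measured_rgb)


def measure_gray(
    img: SkinImage,
    tip_roi: ROI,
    nominal_reflectance: float = DEFAULT_NOMINAL_REFLECTANCE,
) -> GrayReference:
    """Measure the gray reference from the tip ROI (per-channel mean).

    A channel mean of zero is a hard error (black frame). A per-channel
    CV at or above :data:`CV_LIMIT` flags the reference as suspect
    (occluded tip) but does not abort.
    """
    if tip_roi.label is not ROILabel.GRAY_TIP:
        raise ValueError(f"tip_roi must be labeled gray_tip, got {tip_roi.label.value}")
    patch = extract_roi(img, tip_roi).pixels
    means = patch.mean(axis=(0, 1))
    if np.any(means == 0.0):
        raise CalibrationError("gray tip channel mean is zero (black frame)")
    stds = patch.std(axis=(0, 1))
    cvs = stds / means
    suspect = bool(np.any(cvs >= CV_LIMIT))
    if suspect:
        warnings.warn(
            f"gray tip CV {tuple(np.round(cvs, 3))} >= {CV_LIMIT}: occluded tip suspected",
            stacklevel=2,
        )
    return GrayReference(
        measured_rgb=tuple(float(m) for m in means),
        nominal_reflectance=nominal_reflectance,
        cv_rgb=tuple(float(c) for c in cvs),
        suspect=suspect,
    )


def calibrate(img: SkinImage, ref: GrayReference) -> SkinImage:
    """Apply per-channel gains so the gray tip maps to its nominal level.

    The result is clipped to [0, 1]; the number of clipped pixels is
    recorded on the returned image (silent saturation would bias the
    downstream metrics).
    """
    if img.color_state != "raw":
        raise ValueError(f"image already {img.color_state}; calibrate expects raw input")
    gains = np.asarray(ref.gains, dtype=np.float64)
    scaled = img.pixels * gains[None, None, :]
    clipped = int(np.count_nonzero((scaled < 0.0) | (scaled > 1.0)))
    return SkinImage(
        pixels=np.clip(scaled, 0.0, 1.0),
        bit_depth_origin=img.bit_depth_origin,
        color_state="calibrated",
        meta=img.meta,
        gains=tuple(float(g) for g in gains),
        clipped_px=clipped,
    )
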