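"""Pore detection: circular dark blobs on an edge-enhanced binary image.

Pipeline: Rec. 709 luminance -> difference-of-Gaussians edge enhancement
(signed so dark-in-surround is positive) -> robust binarization -> connected
components screened by area, circularity and contrast. The total accepted
blob area, normalized per ROI area and scaled by 1000, is the pore-area
metric in arbitrary units.

Perimeters use the weighted border-pixel estimator of
``skimage.measure.perimeter`` (4-neighborhood); circularity is
``4*pi*A / P**2`` capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.measure import label as cc_label
from skimage.measure import perimeter as perimeter_estimate
from skimage.measure import regionprops

from .core_io import ROI, ROILabel, SkinImage, extract_roi

__all__ = [
    "PoreParams",
    "PoreCandidate",
    "PoreResult",
    "luminance",
    "enhance_edges",
    "binarize",
    "detect_pores",
    "pore_area",
]

#: Rec. 709 luma weights applied to calibrated linear RGB.
LUMA_WEIGHTS = np.array([0.2126, 0.7152, 0.0722])

#: Metric scale: au = AU_SCALE * (accepted blob area) / (ROI area).
AU_SCALE = 1000.0


def luminance(pixels: np.ndarray) -> np.ndarray:
    """Rec. 709 weighted luminance of an (H, W, 3) raster."""
    return np.asarray(pixels, dtype=np.float64) @ LUMA_WEIGHTS


@dataclass(frozen=True)
class PoreParams:
    """Detection parameters; defaults assume a scale of roughly 10 px/mm."""

    dog_sigma_small: float = 1.5
    dog_sigma_large: float = 6.0
    binarize_k: float = 3.0
    min_area: int = 9
    max_area: int = 2000
    circularity_min: float = 0.6
    min_contrast: float = 0.02

    def __post_init__(self) -> None:
        if not self.dog_sigma_small < self.dog_sigma_large:
            raise ValueError("dog_sigma_small must be < dog_sigma_large")
        if not 0.0 < self.circularity_min <= 1.0:
            raise ValueError("circularity_min must be in (0, 1]")
        if not self.min_area < self.max_area:
            raise ValueError("min_area must be < max_area")


@dataclass(frozen=True)
class PoreCandidate:
    centroid: tuple[float, float]
    area_px: int
    perimeter_px: float
    circularity: float
    mean_contrast: float


@dataclass(frozen=True)
class PoreResult:
    candidates: tuple[PoreCandidate, ...]
    total_area_au: float
    roi_area_px: int
    params_used: PoreParams = field(default_factory=PoreParams)

    @property
    def n_pores(self) -> int:
        return len(self.candidates)


def enhance_edges(lum: np.ndarray, sigma_small: float = 1.5, sigma_large: float = 6.0) -> np.ndarray:
    """Difference-of-Gaussians response, positive where darker than surround.

    ``DoG = G(sigma_large)*lum - G(sigma_small)*lum``. The kernel is DC-free,
    so a constant raster maps to zero and additive offsets are ignored.
    """
    lum = np.asarray(lum, dtype=np.float64)
    if lum.ndim != 2:
        raise ValueError(f"expected 2-D luminance raster, got shape {lum.shape}")
    min_side = int(np.ceil(6 * sigma_large))
    if min(lum.shape) < min_side:
        raise ValueError(
            f"raster sides must be >= 6*sigma_large = {min_side}px, got {lum.shape}"
        )
    return gaussian_filter(lum, sigma_large, mode="nearest") - gaussian_filter(
        lum, sigma_small, mode="nearest"
    )


def binarize(resp: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Threshold at ``median + k * 1.4826 * MAD`` (robust to blob outliers)."""
    resp = np.asarray(resp, dtype=np.float64)
    med = np.median(resp)
    mad = np.median(np.abs(resp - med))
    return resp > med + k * 1.4826 * mad


def component_perimeter(component_mask: np.ndarray) -> float:
    """Perimeter of a single binary component (weighted border estimator)."""
    return float(perimeter_estimate(component_mask, neighborhood=4))


def detect_pores(
    mask: np.ndarray, lum: np.ndarray, params: PoreParams | None = None
) -> list[PoreCandidate]:
    """Label the mask 8-connected and screen components by shape and contrast.

    Components touching the ROI border are discarded. Output is sorted by
    area descending, ties broken by centroid (row, col).
    """
    params = params or PoreParams()
    mask = np.asarray(mask, dtype=bool)
    lum = np.asarray(lum, dtype=np.float64)
    if mask.shape != lum.shape:
        raise ValueError("mask and luminance raster must share a shape")
    labels = cc_label(mask, connectivity=2)
    if labels.max() == 0:
        return []
    roi_mean_lum = float(lum.mean())
    h, w = mask.shape
    out: list[PoreCandidate] = []
    for prop in regionprops(labels):
        r0, c0, r1, c1 = prop.bbox
        if r0 == 0 or c0 == 0 or r1 == h or c1 == w:
            continue  # border rule
        area = int(prop.area)
        if not params.min_area <= area <= params.max_area:
            continue
        comp = labels[r0:r1, c0:c1] == prop.label
        perim = component_perimeter(comp)
        circ = 1.0 if perim == 0.0 else min(1.0, 4.0 * np.pi * area / perim**2)
        if circ < params.circularity_min:
            continue
        contrast = roi_mean_lum - float(lum[r0:r1, c0:c1][comp].mean())
        if contrast < params.min_contrast:
            continue
        out.append(
            PoreCandidate(
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                area_px=area,
                perimeter_px=perim,
                circularity=float(circ),
                mean_contrast=contrast,
            )
        )
    out.sort(key=lambda c: (-c.area_px, c.centroid[0], c.centroid[1]))
    return out


def pore_area(img: SkinImage, roi: ROI, params: PoreParams | None = None) -> PoreResult:
    """Run the full pore pipeline on the cheek ROI of a calibrated image."""
    params = params or PoreParams()
    if img.color_state != "calibrated":
        raise ValueError("pore_area requires a calibrated image")
    if roi.label is not ROILabel.CHEEK:
        raise ValueError(f"pore_area expects a cheek ROI, got {roi.label.value}")
    patch = extract_roi(img, roi)
    lum = luminance(patch.pixels)
    resp = enhance_edges(lum, params.dog_sigma_small, params.dog_sigma_large)
    mask = binarize(resp, params.binarize_k)
    candidates = detect_pores(mask, lum, params)
    total = sum(c.area_px for c in candidates)
    return PoreResult(
        candidates=tuple(candidates),
        total_area_au=AU_SCALE * total / roi.area_px,
        roi_area_px=roi.area_px,
        params_used=params,
    )
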