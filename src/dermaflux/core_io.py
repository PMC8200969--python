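"""Image and metric-table I/O, ROI handling, and the shared data model.

All rasters are row-major, 0-based; ROI bounds are half-open ``[start, stop)``.
Pixel intensities are stored as float64 scaled to ``[0, 1]`` by dividing by
``2**bit_depth - 1`` at read time.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "TimePoint",
    "FaceSide",
    "Metric",
    "CaptureMetadata",
    "SkinImage",
    "ROI",
    "MetricRecord",
    "FormatError",
    "BoundsError",
    "week_from_day",
    "read_image",
    "extract_roi",
    "write_records",
    "read_records",
    "records_to_frame",
    "frame_to_records",
]


class FormatError(ValueError):
    """Raised for undecodable or wrong-shape image files."""


class BoundsError(ValueError):
    """Raised when an ROI falls outside its image."""


class TimePoint(str, enum.Enum):
    """The three daily capture sessions."""

    MORNING_WAKE = "morning_wake"
    MORNING_WASH = "morning_wash"
    EVENING_WASH = "evening_wash"


TIMEPOINT_ORDER: tuple[TimePoint, ...] = (
    TimePoint.MORNING_WAKE,
    TimePoint.MORNING_WASH,
    TimePoint.EVENING_WASH,
)


class FaceSide(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class Metric(str, enum.Enum):
    PORE_AREA = "pore_area"
    ROUGHNESS = "roughness"
    REDNESS = "redness"


class ROILabel(str, enum.Enum):
    CHEEK = "cheek"
    EYE_TO_CHEEK = "eye_to_cheek"
    GRAY_TIP = "gray_tip"


def week_from_day(study_day: int) -> int:
    """Map a study day (1..56) to its week index (-4..-1 then 1..4).

    Days 1-28 are the baseline weeks -4..-1; days 29-56 are the
    treatment weeks 1..4. Week 0 does not exist.
    """
    if not 1 <= study_day <= 56:
        raise ValueError(f"study_day must be in 1..56, got {study_day}")
    if study_day <= 28:
        return -4 + (study_day - 1) // 7
    return 1 + (study_day - 29) // 7


@dataclass(frozen=True)
class CaptureMetadata:
    """Identifies one capture: who, when in the study, and which session."""

    subject_id: str
    study_day: int
    timepoint: TimePoint
    face_side: FaceSide = FaceSide.LEFT

    def __post_init__(self) -> None:
        # week_from_day validates the day range
        week_from_day(self.study_day)
        object.__setattr__(self, "timepoint", TimePoint(self.timepoint))
        object.__setattr__(self, "face_side", FaceSide(self.face_side))

    @property
    def week_index(self) -> int:
        return week_from_day(self.study_day)


@dataclass
class SkinImage:
    """A calibratable RGB raster plus its capture metadata.

    ``pixels`` is an ``(H, W, 3)`` float64 array in ``[0, 1]``.
    ``color_state`` transitions only ``raw`` -> ``calibrated``.
    """

    pixels: np.ndarray
    bit_depth_origin: int
    color_state: str
    meta: CaptureMetadata | None = None
    gains: tuple[float, float, float] | None = None
    clipped_px: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError(f"expected (H, W, 3) raster, got shape {px.shape}")
        # full captures must be >= 64x64; ROI crops may go down to the 32x32
        # minimum ROI area, so the hard floor here is the ROI minimum
        if px.shape[0] < 32 or px.shape[1] < 32:
            raise FormatError(f"raster must be at least 32x32, got {px.shape[:2]}")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("pixel values must lie in [0, 1]")
        if self.bit_depth_origin not in (8, 16):
            raise ValueError(f"bit_depth_origin must be 8 or 16, got {self.bit_depth_origin}")
        if self.color_state not in ("raw", "calibrated"):
            raise ValueError(f"unknown color_state {self.color_state!r}")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class ROI:
    """Half-open pixel bounds ``[row_start, row_stop) x [col_start, col_stop)``."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int
    label: ROILabel = ROILabel.CHEEK

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", ROILabel(self.label))
        if self.row_start < 0 or self.col_start < 0:
            raise BoundsError(f"negative ROI start: ({self.row_start}, {self.col_start})")
        h = self.row_stop - self.row_start
        w = self.col_stop - self.col_start
        if h < 32 or w < 32:
            raise BoundsError(f"ROI must span at least 32x32 px, got {h}x{w}")

    @property
    def height(self) -> int:
        return self.row_stop - self.row_start

    @property
    def width(self) -> int:
        return self.col_stop - self.col_start

    @property
    def area_px(self) -> int:
        return self.height * self.width

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row_start, self.row_stop), slice(self.col_start, self.col_stop)


@dataclass(frozen=True)
class MetricRecord:
    """One (subject, day, timepoint, metric) observation in arbitrary units."""

    subject_id: str
    study_day: int
    timepoint: TimePoint
    metric: Metric
    value_au: float
    face_side: str = "both"

    def __post_init__(self) -> None:
        object.__setattr__(self, "timepoint", TimePoint(self.timepoint))
        object.__setattr__(self, "metric", Metric(self.metric))
        if not np.isfinite(self.value_au):
            raise ValueError("value_au must be finite")
        week_from_day(self.study_day)

    @property
    def week_index(self) -> int:
        return week_from_day(self.study_day)


RECORD_COLUMNS = [
    "subject_id",
    "study_day",
    "week_index",
    "timepoint",
    "face_side",
    "metric",
    "value_au",
]


def read_image(path: str | os.PathLike, meta: CaptureMetadata | None = None) -> SkinImage:
    """Read a PNG/JPEG/TIFF into a raw :class:`SkinImage`.

    8-bit values divide by 255, 16-bit by 65535, so full scale maps to 1.0.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # undecodable content
        raise OSError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 2:
        raise FormatError(f"{path}: expected 3 channels, got 1 (grayscale)")
    if arr.ndim != 3 or arr.shape[2] != 3:
        nch = arr.shape[2] if arr.ndim == 3 else arr.ndim
        raise FormatError(f"{path}: expected 3 channels, got {nch}")
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise FormatError(f"{path}: unsupported sample type {arr.dtype}")
    if arr.shape[0] < 64 or arr.shape[1] < 64:
        raise FormatError(f"{path}: capture must be at least 64x64, got {arr.shape[:2]}")
    pixels = arr.astype(np.float64) / (2**depth - 1)
    return SkinImage(pixels=pixels, bit_depth_origin=depth, color_state="raw", meta=meta)


def write_image(img: SkinImage, path: str | os.PathLike) -> None:
    """Quantize back to the origin bit depth and write (format from suffix)."""
    levels = 2**img.bit_depth_origin - 1
    dtype = np.uint8 if img.bit_depth_origin == 8 else np.uint16
    arr = np.rint(np.clip(img.pixels, 0.0, 1.0) * levels).astype(dtype)
    iio.imwrite(Path(path), arr)


def extract_roi(img: SkinImage, roi: ROI) -> SkinImage:
    """Crop ``img`` to ``roi``; metadata and color state are preserved."""
    h, w = img.shape
    if roi.row_stop > h:
        raise BoundsError(f"row_stop {roi.row_stop} exceeds image height {h}")
    if roi.col_stop > w:
        raise BoundsError(f"col_stop {roi.col_stop} exceeds image width {w}")
    rs, cs = roi.slices()
    return SkinImage(
        pixels=img.pixels[rs, cs].copy(),
        bit_depth_origin=img.bit_depth_origin,
        color_state=img.color_state,
        meta=img.meta,
        gains=img.gains,
        clipped_px=img.clipped_px,
    )


def records_to_frame(records: Sequence[MetricRecord]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": r.subject_id,
            "study_day": r.study_day,
            "week_index": r.week_index,
            "timepoint": r.timepoint.value,
            "face_side": r.face_side,
            "metric": r.metric.value,
            "value_au": r.value_au,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[MetricRecord]:
    return [
        MetricRecord(
            subject_id=str(row.subject_id),
            study_day=int(row.study_day),
            timepoint=TimePoint(row.timepoint),
            metric=Metric(row.metric),
            value_au=float(row.value_au),
            face_side=str(row.face_side),
        )
        for row in df.itertuples()
    ]


def write_records(records: Sequence[MetricRecord], path: str | os.PathLike) -> None:
    """Write records to CSV; round-trips losslessly with :func:`read_records`."""
    if len(records) == 0:
        raise ValueError("records must be nonempty")
    path = Path(path)
    if not path.parent.exists():
        raise OSError(f"directory does not exist: {path.parent}")
    records_to_frame(records).to_csv(path, index=False)


def read_records(path: str | os.PathLike) -> list[MetricRecord]:
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"records CSV missing columns: {sorted(missing)}")
    return frame_to_records(df)
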