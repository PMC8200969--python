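"""Batch orchestration: sidecar-driven calibration and metric extraction.

One sidecar CSV row per image file (columns: filename, subject_id,
study_day, timepoint, face_side). Left/right images of a session are
analyzed separately and averaged into a single record per metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import calibrate, measure_gray
from .config import roi_from_config
from .core_io import (
    CaptureMetadata,
    FaceSide,
    Metric,
    MetricRecord,
    TimePoint,
    read_image,
)
from .pores import PoreParams, pore_area
from .redness import redness_score
from .roughness import roughness_score

__all__ = ["BatchResult", "analyze_batch", "SIDECAR_COLUMNS"]

log = logging.getLogger("dermaflux.batch")

SIDECAR_COLUMNS = ["filename", "subject_id", "study_day", "timepoint", "face_side"]

#: Exit-code policy: 0 clean, 1 hard error, 2 completed with skips.
EXIT_CLEAN, EXIT_ERROR, EXIT_SKIPS = 0, 1, 2


@dataclass
class BatchResult:
    records: list[MetricRecord]
    qc: pd.DataFrame
    skipped: list[str]

    @property
    def exit_code(self) -> int:
        return EXIT_SKIPS if self.skipped else EXIT_CLEAN


def _read_sidecar(sidecar_csv: str | Path) -> pd.DataFrame:
    df = pd.read_csv(sidecar_csv, dtype={"subject_id": str})
    if df.empty:
        raise ValueError(f"sidecar is empty: {sidecar_csv}")
    missing = set(SIDECAR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sidecar missing columns: {sorted(missing)}")
    return df


def _parse_row(row, idx: int) -> CaptureMetadata:
    try:
        return CaptureMetadata(
            subject_id=str(row.subject_id),
            study_day=int(row.study_day),
            timepoint=TimePoint(row.timepoint),
            face_side=FaceSide(row.face_side),
        )
    except (ValueError, TypeError) as exc:
        raise ValueError(f"malformed sidecar row {idx}: {exc}") from exc


def analyze_batch(image_dir: str | Path, sidecar_csv: str | Path, config: dict) -> BatchResult:
    """Calibrate and score every image listed in the sidecar.

    Missing files are skipped (listed in the result); malformed sidecar rows
    are hard errors naming the row. Per-session metric values are the mean
    over the sides present.
    """
    image_dir = Path(image_dir)
    sidecar = _read_sidecar(sidecar_csv)

    tip_roi = roi_from_config(config["calibration"]["tip_roi"], "gray_tip")
    cheek_roi = roi_from_config(config["rois"]["cheek"], "cheek")
    eye_roi = roi_from_config(config["rois"]["eye_to_cheek"], "eye_to_cheek")
    pparams = PoreParams(**config["pores"])
    rough_cfg = config["roughness"]
    red_cfg = config["redness"]

    skipped: list[str] = []
    qc_rows = []
    per_image = []  # (meta, metric, value)
    for idx, row in enumerate(sidecar.itertuples()):
        meta = _parse_row(row, idx)
        path = image_dir / str(row.filename)
        if not path.exists():
            log.warning("missing image file, skipping: %s", path)
            skipped.append(str(row.filename))
            continue
        img = read_image(path, meta)
        ref = measure_gray(img, tip_roi, config["calibration"]["nominal_reflectance"])
        cal = calibrate(img, ref)
        pres = pore_area(cal, cheek_roi, pparams)
        rres = roughness_score(cal, eye_roi, tuple(rough_cfg["band"]), rough_cfg["sigma_illum"])
        dres = redness_score(
            cal,
            cheek_roi,
            tuple(red_cfg["band"]),
            red_cfg["w_brightness"],
            red_cfg["w_variation"],
        )
        values = {
            Metric.PORE_AREA: pres.total_area_au,
            Metric.ROUGHNESS: rres.roughness_au,
            Metric.REDNESS: dres.redness_au,
        }
        for metric, value in values.items():
            per_image.append((meta, metric, value))
        qc_rows.append(
            {
                "filename": str(row.filename),
                "clipped_px": cal.clipped_px,
                "tip_cv_max": max(ref.cv_rgb),
                "tip_suspect": ref.suspect,
                "n_pores": pres.n_pores,
            }
        )

    # side-average into one record per (subject, day, timepoint, metric)
    grouped: dict[tuple, list[float]] = {}
    for meta, metric, value in per_image:
        key = (meta.subject_id, meta.study_day, meta.timepoint, metric)
        grouped.setdefault(key, []).append(value)
    records = [
        MetricRecord(
            subject_id=subject,
            study_day=day,
            timepoint=tp,
            metric=metric,
            value_au=float(np.mean(vals)),
            face_side="both",
        )
        for (subject, day, tp, metric), vals in sorted(
            grouped.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2].value, kv[0][3].value)
        )
    ]
    qc = pd.DataFrame(qc_rows, columns=["filename", "clipped_px", "tip_cv_max", "tip_suspect", "n_pores"])
    return BatchResult(records=records, qc=qc, skipped=skipped)
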