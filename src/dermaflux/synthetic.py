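"""Synthetic skin patches with ground truth, and simulated longitudinal cohorts.

Patches compose, in order: base tone, multiplicative illumination gradient,
exact-RMS in-band relative texture, anti-aliased dark pore disks, a blotch
field applied to the R/G ratio in log10 units, the painted gray tip, and
per-channel gains, then quantization to the requested bit depth. Everything
is reproducible from the seed.

Cohorts follow the study schedule (8 weeks x 7 days x 3 sessions) with the
value model ``value = mu + b_s + tau_t + delta_t * 1[week >= 1] + eps``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._spectral import band_limited_field
from .core_io import (
    RECORD_COLUMNS,
    ROI,
    ROILabel,
    SkinImage,
    TIMEPOINT_ORDER,
    Metric,
    week_from_day,
    write_image,
)

__all__ = [
    "PatchParams",
    "GroundTruth",
    "MetricModel",
    "CohortParams",
    "FeasibilityError",
    "generate_patch",
    "generate_cohort",
    "DEFAULT_METRIC_MODELS",
]

PLACEMENT_MARGIN = 5  # px between any pore edge and the frame border
PORE_GAP = 2  # px minimum edge-to-edge distance between pores
MAX_REJECTION_ROUNDS = 10_000

DEVICE_PRESET_SIZE = (1080, 1920)  # capture-resolution emulation


class FeasibilityError(RuntimeError):
    """Pore placement could not satisfy the spacing constraints."""


@dataclass(frozen=True)
class PatchParams:
    size: tuple[int, int] = (512, 512)
    base_rgb: tuple[float, float, float] = (0.55, 0.42, 0.35)
    n_pores: int = 0
    pore_radius_mean: float = 5.0
    pore_radius_sd: float = 0.0
    pore_contrast: float = 0.15
    texture_rms: float = 0.0
    texture_band: tuple[float, float] = (0.02, 0.15)
    blotch_rms: float = 0.0
    blotch_mean: float = 0.0
    blotch_band: tuple[float, float] = (0.005, 0.05)
    illum_gradient: float = 0.0
    pore_region: ROI | None = None  # placement bounds; None = whole frame
    tip_roi: ROI | None = None
    tip_reflectance: float = 0.5
    gains: tuple[float, float, float] = (1.0, 1.0, 1.0)
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pore_contrast", "texture_rms", "blotch_rms", "illum_gradient"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_pores < 0:
            raise ValueError("n_pores must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Generator-side truth for recovery tests."""

    pore_area_fraction: float
    pores: tuple[tuple[float, float, float], ...]  # (row, col, radius)
    texture_rms: float
    blotch_rms: float
    blotch_mean: float
    gains: tuple[float, float, float]


def _place_pores(
    rng: np.random.Generator, params: PatchParams
) -> list[tuple[float, float, float]]:
    h, w = params.size
    region = params.pore_region
    r0, r1 = (region.row_start, region.row_stop) if region else (0, h)
    c0, c1 = (region.col_start, region.col_stop) if region else (0, w)
    placed: list[tuple[float, float, float]] = []
    rounds = 0
    tip = params.tip_roi
    while len(placed) < params.n_pores:
        if rounds >= MAX_REJECTION_ROUNDS:
            raise FeasibilityError(
                f"placed only {len(placed)}/{params.n_pores} pores in {rounds} rounds"
            )
        rounds += 1
        r = max(1.0, rng.normal(params.pore_radius_mean, params.pore_radius_sd))
        lo = PLACEMENT_MARGIN + r
        row = rng.uniform(r0 + lo, r1 - 1 - lo)
        col = rng.uniform(c0 + lo, c1 - 1 - lo)
        if tip is not None:
            pad = r + PORE_GAP
            if (
                tip.row_start - pad <= row < tip.row_stop + pad
                and tip.col_start - pad <= col < tip.col_stop + pad
            ):
                continue
        ok = all(
            np.hypot(row - pr, col - pc) >= r + pr2 + PORE_GAP
            for pr, pc, pr2 in placed
        )
        if ok:
            placed.append((row, col, r))
    return placed


def _stamp_coverage(shape: tuple[int, int], pores) -> np.ndarray:
    """Anti-aliased disk coverage in [0, 1] (linear edge ramp of 1 px)."""
    cov = np.zeros(shape)
    for row, col, r in pores:
        pad = int(np.ceil(r)) + 2
        r0, r1 = max(0, int(row) - pad), min(shape[0], int(row) + pad + 1)
        c0, c1 = max(0, int(col) - pad), min(shape[1], int(col) + pad + 1)
        rr = np.arange(r0, r1)[:, None] - row
        cc = np.arange(c0, c1)[None, :] - col
        dist = np.hypot(rr, cc)
        cov[r0:r1, c0:c1] = np.maximum(
            cov[r0:r1, c0:c1], np.clip(r - dist + 0.5, 0.0, 1.0)
        )
    return cov


def generate_patch(params: PatchParams) -> tuple[SkinImage, GroundTruth]:
    """Render a synthetic skin patch and return it with its ground truth."""
    rng = np.random.default_rng(params.seed)
    h, w = params.size

    texture = band_limited_field((h, w), params.texture_band, params.texture_rms, rng)
    pores = _place_pores(rng, params) if params.n_pores else []
    blotch = params.blotch_mean + band_limited_field(
        (h, w), params.blotch_band, params.blotch_rms, rng
    )

    ramp = (np.arange(h, dtype=np.float64) / max(h - 1, 1) - 0.5)[:, None]
    illum = 1.0 + params.illum_gradient * ramp  # +-gradient/2 across rows
    shade = illum * (1.0 + texture)
    if pores:
        shade = shade * (1.0 - params.pore_contrast * _stamp_coverage((h, w), pores))

    base = np.asarray(params.base_rgb, dtype=np.float64)
    px = np.empty((h, w, 3))
    px[..., 0] = base[0] * shade * 10.0 ** (blotch / 2.0)
    px[..., 1] = base[1] * shade * 10.0 ** (-blotch / 2.0)
    px[..., 2] = base[2] * shade
    # renormalize the blotch to be luminance-neutral: it shifts log10(R/G)
    # by exactly `blotch` but leaves Rec.709 luminance untouched, so redness
    # structure cannot leak into the pore/roughness channels
    w709 = np.array([0.2126, 0.7152, 0.0722])
    lum_neutral = (base @ w709) * shade
    px *= (lum_neutral / (px @ w709))[..., None]

    if params.tip_roi is not None:
        rs, cs = params.tip_roi.slices()
        px[rs, cs, :] = params.tip_reflectance

    px *= np.asarray(params.gains)[None, None, :]
    px = np.clip(px, 0.0, 1.0)
    levels = 2**params.bit_depth - 1
    px = np.rint(px * levels) / levels

    img = SkinImage(pixels=px, bit_depth_origin=params.bit_depth, color_state="raw")
    region_area = params.pore_region.area_px if params.pore_region else h * w
    truth = GroundTruth(
        pore_area_fraction=float(sum(np.pi * r**2 for _, _, r in pores)) / region_area,
        pores=tuple((float(a), float(b), float(c)) for a, b, c in pores),
        texture_rms=params.texture_rms,
        blotch_rms=params.blotch_rms,
        blotch_mean=params.blotch_mean,
        gains=params.gains,
    )
    return img, truth


# --------------------------------------------------------------------------
# Cohort simulation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricModel:
    """Linear value model for one metric (all in arbitrary units)."""

    mu: float
    tau: dict[str, float]  # timepoint offsets
    delta: dict[str, float]  # treatment offsets per timepoint (weeks >= 1)
    sigma_subject: float
    sigma_noise: float


# Effect sizes are invented (the study prints no metric values); they are
# sized so that n = 47 reproduces the reported significance pattern:
# morning-wake largest for pore area and roughness, evening largest for
# redness, and treatment reducing both net values and within-day spread.
DEFAULT_METRIC_MODELS: dict[str, MetricModel] = {
    Metric.PORE_AREA.value: MetricModel(
        mu=100.0,
        tau={"morning_wake": 8.0, "morning_wash": 0.0, "evening_wash": 2.0},
        delta={"morning_wake": -8.0, "morning_wash": -3.0, "evening_wash": -3.0},
        sigma_subject=10.0,
        sigma_noise=4.0,
    ),
    Metric.ROUGHNESS.value: MetricModel(
        mu=100.0,
        tau={"morning_wake": 8.0, "morning_wash": 0.0, "evening_wash": 2.0},
        delta={"morning_wake": -8.0, "morning_wash": -3.0, "evening_wash": -3.0},
        sigma_subject=10.0,
        sigma_noise=4.0,
    ),
    Metric.REDNESS.value: MetricModel(
        mu=100.0,
        tau={"morning_wake": 1.0, "morning_wash": 0.0, "evening_wash": 6.0},
        delta={"morning_wake": -3.0, "morning_wash": -3.0, "evening_wash": -8.0},
        sigma_subject=10.0,
        sigma_noise=4.0,
    ),
}


@dataclass(frozen=True)
class CohortParams:
    n_subjects: int = 47
    days_per_week: int = 7
    models: dict[str, MetricModel] = field(
        default_factory=lambda: dict(DEFAULT_METRIC_MODELS)
    )
    missingness: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.days_per_week <= 7:
            raise ValueError("days_per_week must be in 1..7")
        if not 0.0 <= self.missingness < 1.0:
            raise ValueError("missingness must be in [0, 1)")


def _schedule_days(days_per_week: int) -> list[int]:
    days = []
    for week_start in range(0, 56, 7):
        days.extend(range(week_start + 1, week_start + 1 + days_per_week))
    return days


def generate_cohort(
    params: CohortParams,
    mode: str = "values",
    out_dir: str | Path | None = None,
    image_size: tuple[int, int] = (256, 256),
) -> pd.DataFrame:
    """Simulate a cohort; returns the metric-record table.

    ``values`` mode emits the linear-model values directly. ``images`` mode
    additionally renders one patch per session into ``out_dir`` (16-bit TIFF,
    with gray tip) plus a ``sidecar.csv`` mapping files to sessions; the
    returned table then holds the *generating* values for reference. Rendered
    frames need ``image_size`` of at least (256, 256) for the default pore
    density to stay placeable in the cheek region.
    Sessions are dropped independently with probability ``missingness``
    (the whole session: all metrics at once).
    """
    if mode not in ("values", "images"):
        raise ValueError(f"mode must be 'values' or 'images', got {mode!r}")
    if mode == "images" and out_dir is None:
        raise ValueError("images mode requires out_dir")
    rng = np.random.default_rng(params.seed)
    metrics = list(params.models)
    subjects = [f"S{i + 1:03d}" for i in range(params.n_subjects)]
    b = {
        m: rng.normal(0.0, params.models[m].sigma_subject, params.n_subjects)
        for m in metrics
    }
    days = _schedule_days(params.days_per_week)

    rows = []
    sessions = []  # (subject, day, timepoint, {metric: value}) for image mode
    for si, subject in enumerate(subjects):
        for day in days:
            treated = week_from_day(day) >= 1
            for tp in TIMEPOINT_ORDER:
                if params.missingness > 0 and rng.uniform() < params.missingness:
                    continue
                values = {}
                for m in metrics:
                    model = params.models[m]
                    val = (
                        model.mu
                        + b[m][si]
                        + model.tau.get(tp.value, 0.0)
                        + (model.delta.get(tp.value, 0.0) if treated else 0.0)
                        + rng.normal(0.0, model.sigma_noise)
                    )
                    values[m] = val
                    rows.append(
                        {
                            "subject_id": subject,
                            "study_day": day,
                            "week_index": week_from_day(day),
                            "timepoint": tp.value,
                            "face_side": "both",
                            "metric": m,
                            "value_au": val,
                        }
                    )
                sessions.append((subject, day, tp.value, values))

    table = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    if mode == "images":
        _render_cohort_images(sessions, Path(out_dir), image_size, params.seed)
    return table


# Mapping from generating au values to patch parameters (monotone by design;
# absolute au scales are not preserved, only ordering).
_PORE_AU_PER_PORE = 3.0  # 100 au -> 33 pores
_ROUGH_AU_TO_RMS = 1e-4  # 100 au -> texture_rms 0.01
_RED_AU_TO_MEAN_H = 1e-3  # 100 au -> mean h shift 0.1
_RED_AU_TO_BLOTCH_RMS = 5e-4  # 100 au -> blotch rms 0.05
_IMAGE_PORE_RADIUS = 4.0
# deep pores: keeps detected area insensitive to the session's texture
# amplitude (which scales the robust binarization threshold)
_IMAGE_PORE_CONTRAST = 0.3


def default_tip_roi(size: tuple[int, int]) -> ROI:
    """Gray tip in the top-left corner, 32x32 minimum."""
    side = max(32, min(size) // 8)
    return ROI(0, side, 0, side, label=ROILabel.GRAY_TIP)


def image_mode_layout(size: tuple[int, int]) -> dict[str, ROI]:
    """Fixed in-frame layout for rendered sessions.

    Pores live only in the cheek region (lower half); roughness is read from
    a pore-free eye-to-cheek band above it, mirroring the study's anatomy and
    keeping the three metrics separable in the rendered scene.
    """
    h, w = size
    tip = default_tip_roi(size)
    mid = (tip.row_stop + h) // 2
    eye = ROI(tip.row_stop + 4, mid - 4, 8, w - 8, label=ROILabel.EYE_TO_CHEEK)
    cheek = ROI(mid + 4, h - 8, 8, w - 8, label=ROILabel.CHEEK)
    return {"gray_tip": tip, "eye_to_cheek": eye, "cheek": cheek}


def patch_params_for_values(
    pore_au: float,
    rough_au: float,
    red_au: float,
    size: tuple[int, int] = (256, 256),
    seed: int = 0,
    tip_roi: ROI | None = None,
    pore_region: ROI | None = None,
) -> PatchParams:
    """Map one session's generating values to renderable patch parameters."""
    return PatchParams(
        size=size,
        n_pores=max(0, int(round(pore_au / _PORE_AU_PER_PORE))),
        pore_radius_mean=_IMAGE_PORE_RADIUS,
        pore_radius_sd=0.0,
        pore_contrast=_IMAGE_PORE_CONTRAST,
        texture_rms=max(0.0, rough_au) * _ROUGH_AU_TO_RMS,
        blotch_rms=max(0.0, red_au) * _RED_AU_TO_BLOTCH_RMS,
        blotch_mean=red_au * _RED_AU_TO_MEAN_H,
        pore_region=pore_region,
        tip_roi=tip_roi,
        seed=seed,
    )


def _render_cohort_images(sessions, out_dir: Path, size, seed: int) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    layout = image_mode_layout(size)
    sidecar_rows = []
    for i, (subject, day, tp, values) in enumerate(sessions):
        p = patch_params_for_values(
            values.get(Metric.PORE_AREA.value, 0.0),
            values.get(Metric.ROUGHNESS.value, 0.0),
            values.get(Metric.REDNESS.value, 0.0),
            size=size,
            seed=seed * 1_000_003 + i,
            tip_roi=layout["gray_tip"],
            pore_region=layout["cheek"],
        )
        img, _ = generate_patch(p)
        # TIFF keeps 16-bit RGB exactly (PNG writers may narrow to 8-bit)
        fname = f"{subject}_d{day:02d}_{tp}_left.tiff"
        write_image(img, out_dir / fname)
        sidecar_rows.append(
            {
                "filename": fname,
                "subject_id": subject,
                "study_day": day,
                "timepoint": tp,
                "face_side": "left",
            }
        )
    pd.DataFrame(sidecar_rows).to_csv(out_dir / "sidecar.csv", index=False)
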