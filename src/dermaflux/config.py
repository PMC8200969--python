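"""Run configuration: YAML-backed, defaults-merged, unknown keys rejected.

Every run writes the fully-resolved configuration next to its outputs so a
result is always reproducible from the artifacts alone.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .core_io import ROI, ROILabel

__all__ = ["DEFAULT_CONFIG", "load_config", "dump_config", "roi_from_config"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "log_level": "INFO",
    "calibration": {
        "tip_roi": [0, 32, 0, 32],
        "nominal_reflectance": 0.5,
    },
    "rois": {
        "cheek": [64, 256, 64, 256],
        "eye_to_cheek": [64, 256, 64, 256],
    },
    "pores": {
        "dog_sigma_small": 1.5,
        "dog_sigma_large": 6.0,
        "binarize_k": 3.0,
        "min_area": 9,
        "max_area": 2000,
        "circularity_min": 0.6,
        "min_contrast": 0.02,
    },
    "roughness": {
        "band": [0.02, 0.15],
        "sigma_illum": 30.0,
    },
    "redness": {
        "band": [0.005, 0.05],
        "w_brightness": 1.0,
        "w_variation": 1.0,
    },
    "fluctuation": {
        "baseline": "week-4",
        "adjust": True,
    },
    "synthetic": {
        "n_subjects": 47,
        "days_per_week": 7,
        "missingness": 0.0,
        "image_size": [256, 256],
    },
}


class ConfigError(ValueError):
    pass


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config key {here} must be a mapping")
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load YAML config merged over defaults; unknown keys are rejected."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"config root must be a mapping, got {type(user).__name__}")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def dump_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def roi_from_config(bounds, label: str | ROILabel) -> ROI:
    r0, r1, c0, c1 = (int(v) for v in bounds)
    return ROI(r0, r1, c0, c1, label=ROILabel(label))
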