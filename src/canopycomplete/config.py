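"""YAML pipeline configuration: nested sections with defaults, lossless
round-tripping, and config hashing for artifact provenance."""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "seed": 0,
    "archetypes": {},          # per-stage overrides of the built-in archetypes
    "layout": {"rows": 4, "cols": 4, "row_spacing": 28.0,
               "plant_spacing": 25.0, "position_jitter": 0.0},
    "rig": {"distance_m": 5.0, "view_angle_deg": -60.0, "azimuth_step_deg": 10.0},
    "annotation": {"dedup_threshold_cm": 0.1},
    "dataset": {"stages": ["seedling", "bolting", "flowering", "silique"],
                "n_scenes_per_stage": 4, "pool_size": 8,
                "train_fraction": 0.8},
    "blocks": {"n_blocks": 8, "block_size": 8192, "overlap_fraction": 0.0},
    "model": {"k_neighbors": 20, "width_scale": 1.0},
    "training": {"learning_rate": 1.0e-4, "batch_size": 8, "max_epochs": 200,
                 "stop_loss": 0.1, "val_every": 10,
                 "lambda_com": 0.9, "lambda_adv": 0.1},
    "metrics": {"ssim3d_feature": "local_density", "ssim3d_radius_cm": 2.0},
    "traits": {"voxel_size_mm": 3.0},
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown config key: {where}")
        if isinstance(base[key], dict) and path != "archetypes" and key != "archetypes":
            if not isinstance(value, dict):
                raise ValueError(f"config section {where} must be a mapping")
            out[key] = _merge(base[key], value, where)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults overlaid with a YAML file; unknown keys raise KeyError."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _merge(DEFAULTS, data)


def save_config(config: dict, path: str | Path):
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]
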