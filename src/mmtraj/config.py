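"""Run configuration: nested defaults, strict validation, YAML round-trip."""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any

import yaml

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 42,
    "output_dir": "mmtraj_out",
    "input": {
        "table": None,
        "metadata": None,
        "format": "csv",
        "orientation": "samples_as_rows",
        "time_unit": "",
    },
    "synthetic": {
        "n_subjects": 40,
        "samples_per_subject": 8,
        "n_features": 30,
        "n_informative": 5,
        "effect_size": 1.0,
        "noise_sd": 0.3,
        "group_shift": 0.0,
        "anomaly_frac": 0.0,
        "anomaly_magnitude": 0.0,
    },
    "exploration": {"n_bins": 10, "diversity_index": "shannon", "embedding": "pca"},
    "transform": {
        "pseudocount": None,
        "n_bins": 10,
        "variance_quantile": 0.1,
        "correlation_threshold": 0.95,
        "denominator_strategy": "crossings",
        "model_spec": "ridge",
        "reference_mode": "declared",
        "reference_group": None,
    },
    "trajectory": {
        "regressor": "bagged_trees",
        "level": 0.95,
        "interval": "prediction",
        "cv_folds": 5,
        "leaderboard": ["linear", "ridge", "knn", "bagged_trees", "dummy"],
    },
    "anomaly": {
        "window": 5,
        "k": 3.0,
        "contamination": 0.05,
        "subsample_ratio": 1.0,
    },
    "intervention": {"k_max": 10, "bandwidth": None, "max_outliers": 5},
    "stages": {
        "explore": True,
        "transform": True,
        "trajectory": True,
        "anomaly": True,
        "intervene": True,
    },
}


class ConfigError(ValueError):
    """Configuration did not validate."""


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in base:
            raise ConfigError(f"unknown config key {here!r}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Resolve a config: defaults <- YAML file <- explicit overrides.

    Unknown keys anywhere raise :class:`ConfigError` (typo protection).
    """
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        cfg = _merge(cfg, data)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
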