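"""Configuration defaults and YAML loading.

A single nested mapping with flow.*, peaks.*, calcium.* and stats.*
sections; a user YAML overrides defaults key by key. Every run materializes
the resolved config next to its outputs for reproducibility.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "load_config", "dump_config"]

DEFAULTS: dict = {
    "flow": {
        "alpha": 0.1,
        "iterations": 500,
        "tolerance": 1e-5,
        "fraction": 1.0 / 3000.0,
        "reduce": "mean",
    },
    "peaks": {
        "min_rel_amplitude": 0.05,
        "baseline_percentile": 10.0,
        "endpoint_frac": 0.20,
        "max_gap_s": 0.1,
    },
    "calcium": {
        "spark_threshold": 10.0,
        "width_height_frac": 0.10,
        "baseline_percentile": 10.0,
        "background": "temporal_min",
    },
    "stats": {
        "welch": True,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path=None) -> dict:
    """Defaults, optionally overridden by a YAML file."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path, "r", encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config {path} must be a mapping")
    return _merge(DEFAULTS, user)


def dump_config(config: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))
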