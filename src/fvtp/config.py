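"""Default processing configuration and YAML overrides."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "merge_config", "dump_config"]

DEFAULT_CONFIG: dict = {
    "jump": {
        "cutoff_hz": 10.0,
        "onset_sd": 5.0,
        "onset_floor_N": 10.0,
        "flight_threshold_N": 10.0,
    },
    "cycling": {
        "crank_length_m": 0.170,
        "smooth_window_s": 0.5,
    },
    "iso": {
        "cutoff_hz": 5.0,
        "exclusion_fraction": 0.1,
    },
    "stats": {
        "level": 0.95,
    },
}


def merge_config(base: dict, override: dict | None) -> dict:
    """Deep-merge ``override`` into a copy of ``base``."""
    merged = copy.deepcopy(base)
    for key, value in (override or {}).items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key] = merge_config(merged[key], value)
        else:
            merged[key] = value
    return merged


def load_config(path=None) -> dict:
    """Defaults, optionally overridden by a YAML file."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    with open(path) as fh:
        override = yaml.safe_load(fh) or {}
    if not isinstance(override, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return merge_config(DEFAULT_CONFIG, override)


def dump_config(config: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))
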