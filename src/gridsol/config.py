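"""Run configuration: flat YAML file over documented defaults."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULTS: dict = {
    # aggregation
    "block": 10,                  # fine pixels per coarse cell edge
    "min_valid_fraction": 0.5,    # min fraction of valid fine pixels per coarse cell
    "ptf_stage": "fine",          # "fine": PTFs at fine pixels then aggregate;
                                  # "coarse": PTFs on coarse-cell means
    # classification (see gridsol.hc27 for semantics)
    "texture_rule": {
        "clay_min_clay_pct": 40.0,
        "sand_min_sand_pct": 65.0,
        "sand_max_clay_pct": 18.0,
    },
    "fertility_thresholds_pct": {"high": 1.2, "medium": 0.7},
    "depth_lookup_mm": {
        "clay": [150.0, 100.0],
        "loam": [150.0, 75.0],
        "sand": [125.0, 75.0],
    },
    # layer remapping: None = the default scheme
    "layer_weight_scheme": None,
    # output
    "catchall_iso": "ZZ",         # file for cells outside the country mask
    "template_dir": None,         # directory of 27 generic-template *.SOL files
}


class ConfigError(ValueError):
    pass


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge defaults <- YAML file <- overrides (shallow per top-level key;
    dict-valued keys merge per sub-key)."""
    cfg = copy.deepcopy(DEFAULTS)
    layers = []
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        layers.append(loaded)
    if overrides:
        layers.append(overrides)
    for layer in layers:
        for key, value in layer.items():
            if key not in cfg:
                raise ConfigError(f"unknown config key {key!r}")
            if isinstance(cfg[key], dict) and isinstance(value, dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
    if cfg["ptf_stage"] not in ("fine", "coarse"):
        raise ConfigError(f"ptf_stage must be 'fine' or 'coarse', got {cfg['ptf_stage']!r}")
    if not (0.0 < cfg["min_valid_fraction"] <= 1.0):
        raise ConfigError("min_valid_fraction must be in (0, 1]")
    return cfg
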