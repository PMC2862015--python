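"""Run configuration: one TOML document wiring every stage's parameters.

Defaults are the method's canonical values: -135 dB bi-frequency sum
threshold, +2 dB difference threshold, 98 % cumulative threshold, 10^-3
fish weight, 0.75 m elementary cells, 300 pings within 5 km for station
matching, the 0.8 mL L^-1 isoline and a 3.4 m transducer depth.  Unknown
keys are rejected before any compute; flags override config, config
overrides defaults.
"""
from __future__ import annotations

import copy
import tomllib
from pathlib import Path
from typing import Any

DEFAULTS: dict[str, Any] = {
    "logging": {"level": "INFO"},
    "output": {"dir": "veec_out"},
    "noise": {
        "alpha_db_per_m": {"38": 0.0097, "120": 0.0267},
        "offset_db": {"38": None, "120": None},  # None disables noise removal
    },
    "grid": {"cell_height_m": 0.75, "pings_per_cell": 1},
    "diel": {"day_min_elev_deg": 0.0, "night_max_elev_deg": -12.0},
    "discriminate": {"sum_threshold_db": -135.0, "diff_threshold_db": 2.0},
    "zveec": {
        "threshold": 0.98,
        "fish_weight": 1e-3,
        "fish_channel": "38",
        "other_channel": "120",
        "min_energy": 0.0,
    },
    "oxygen": {
        "iso_ml_l": 0.8,
        "omz_conc_ml_l": 0.5,
        "grad_crit_ml_l_m": -0.02,
        "grid_step_m": 1.0,
    },
    "validate": {"min_pings": 300, "max_radius_km": 5.0},
    "habitat": {"resolution_deg": 0.05, "offshore_limit_km": 200.0},
    "wavelet": {"dx_km": 0.1, "omega0": 6.0, "dj": 0.125, "significance_level": 0.95},
    "scene": {},  # free-form SceneSpec overrides for the simulate stage
}


class ConfigError(ValueError):
    """Raised for unknown keys or malformed configuration."""


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if path == "scene":  # SceneSpec validates its own fields
            out[key] = value
            continue
        if key not in defaults:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(defaults[key], dict) and not path.startswith("scene"):
            if not isinstance(value, dict):
                raise ConfigError(f"config key {here} must be a table")
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load a TOML config over the defaults, rejecting unknown keys."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path, "rb") as fh:
            user = tomllib.load(fh)
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg
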