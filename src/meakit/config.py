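"""Batch-analysis configuration: TOML sections mirroring the module
parameter groups, every default pre-filled."""

from __future__ import annotations

import copy
import tomllib
from typing import Any

DEFAULT_CONFIG: dict[str, Any] = {
    "spike_detection": {
        "filter_cutoff_hz": 200.0,
        "filter_order": 2,
        "noise_window_ms": 50.0,
        "pure_noise_stretch_s": 2.0,
        "threshold_factor": 5.0,
        "dead_time_ms": 0.0,
        "min_amplitude_uv": 0.0,
        "min_rate_hz": 0.1,
        "snippet_halfwidth_ms": 1.0,
    },
    "burst": {
        "max_interval": {
            "start_interval_s": 0.05,
            "n_spikes": 3,
            "inter_burst_interval_s": 0.1,
            "intra_burst_interval_s": 0.1,
            "min_burst_duration_s": 0.03,
        },
        "logisi": {
            "n_spikes": 3,
            "void_threshold_pct": 70.0,
        },
    },
    "network_burst": {
        "sync_window_s": 0.1,
        "min_sync_burst_count": 2,
        "min_participation_pct": 25.0,
        "scb_method": "max_interval",
    },
    "connectivity": {
        "enabled": True,
        "chunk_spikes": 10_000,
        "bin_s": 0.0005,
        "max_lag_s": 0.5,
        "snr_factor": 2.0,
    },
    "synchrony": {
        "enabled": True,
        "grid_step_s": 0.001,
    },
    "sorting": {
        "enabled": False,
        "method": "pca",
        "k_over": 8,
        "seed": 0,
    },
    "general": {
        "remove_channels": [],
        "group_mode": "mean",
    },
    "group": {},
}


class ConfigError(ValueError):
    pass


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if path == "group":  # free-form group names
            out[key] = val
            continue
        if key not in base:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"config section {here} must be a table")
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = val
    return out


def load_config(path: str | None = None) -> dict[str, Any]:
    """Load a TOML config merged over the defaults; unknown keys error."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is None:
        return cfg
    with open(path, "rb") as fh:
        user = tomllib.load(fh)
    # allow free-form well-group lists
    groups = user.pop("group", {})
    cfg = _merge(cfg, user)
    cfg["group"] = dict(groups)
    return cfg


def apply_overrides(cfg: dict[str, Any], sets: list[str]) -> dict[str, Any]:
    """Apply ``section.key=value`` command-line overrides."""
    cfg = copy.deepcopy(cfg)
    for item in sets:
        if "=" not in item:
            raise ConfigError(f"override must look like section.key=value: {item!r}")
        dotted, raw = item.split("=", 1)
        keys = dotted.split(".")
        node = cfg
        for k in keys[:-1]:
            if k not in node or not isinstance(node[k], dict):
                raise ConfigError(f"unknown config section: {dotted!r}")
            node = node[k]
        leaf = keys[-1]
        if leaf not in node:
            raise ConfigError(f"unknown config key: {dotted!r}")
        old = node[leaf]
        if isinstance(old, bool):
            node[leaf] = raw.lower() in ("1", "true", "yes")
        elif isinstance(old, int):
            node[leaf] = int(raw)
        elif isinstance(old, float):
            node[leaf] = float(raw)
        elif isinstance(old, list):
            node[leaf] = [s for s in raw.split(",") if s]
        else:
            node[leaf] = raw
    return cfg
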