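"""Run configuration: defaults, YAML loading, validation, hashing.

All thresholds of every stage live here with their standard defaults, so a
run's resolved configuration can be serialized next to its outputs and
hashed into every output table.
"""

from __future__ import annotations

import copy
import hashlib
import json

import yaml

DEFAULTS: dict = {
    "seed": 0,
    "annotation": {
        "or_ids": None,
        "or_regex": "^OR",
        "lnc_ids": None,
        "lnc_regex": "^LNC",
        "max_gap": 10_000,
        "cds_len_bounds": [100, 10_000],
        "intergenic_bounds": [50, 10_000],
    },
    "coverage": {
        "n_pairs": 50,
        "promoter_rate": 50.0,
        "readthrough_decay_per_kb": 0.2,
        "nonor_decay_per_kb": 3.0,
        "antisense_fraction": 0.5,
        "nonor_antisense_fraction": 0.005,
    },
    "tss": {
        "window_bp": 1000,
        "min_reads": 1,
        "sense_offset": [200.0, 60.0],
        "antisense_offset": [500.0, 60.0],
        "reads_per_gene": 50,
        "bidir_fraction": 0.34,
    },
    "sc": {
        "min_markers": 2,
        "min_umi": 2,
        "target_sum": 10_000.0,
        "min_cells": 3,
        "n_cells": 1000,
        "chosen_mean": 100.0,
        "downstream_decay": 1.5,
        "lnc_mean": 30.0,
        "leak_mean": 5.0,
        "lnc_coupling": 0.12,
        "nb_dispersion": 20.0,
        "partner_bias": 1.0,
        "corr_n_lncrnas": 20,
        "corr_n_cells": 500,
    },
    "fish": {
        "sigma": 100.0,
        "min_area": 12,
        "dilate_px": 3,
        "q_low": 0.001,
        "q_high": 0.999,
        "nuclear_signal": 0.75,
        "cytoplasmic_signal": 0.2,
        "nuclear_area": [400, 900],
        "cytoplasmic_area": 100,
        "eccentricity": 0.8,
        "nuclear_thresh": 0.1,
        "n_cells": 12,
        "shape": [6, 2, 256, 256],
        "dapi_attenuation": 0.9,
        "noise": 0.0,
    },
    "synth": {
        "n_arrays": 4,
        "array_size_range": [3, 6],
        "gene_len": 2000,
        "gap_range": [1000, 6000],
        "inversion_rate": 0.0,
        "lnc_per_array": 1,
        "n_nonor_pairs": 8,
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
            _check_type(base[key], value, here)
            out[key] = value
    return out


def _check_type(default, value, key: str) -> None:
    if default is None or value is None:
        return
    if isinstance(default, bool) != isinstance(value, bool):
        raise ConfigError(f"config key {key}: expected {type(default).__name__}")
    if isinstance(default, (int, float)) and isinstance(value, (int, float)):
        return
    if isinstance(default, (list, tuple)) and isinstance(value, (list, tuple)):
        return
    if type(default) is not type(value):
        raise ConfigError(
            f"config key {key}: expected {type(default).__name__}, got {type(value).__name__}"
        )


def load_config(path: str | None = None, overrides: dict | None = None) -> dict:
    """DEFAULTS deep-merged with an optional YAML file and explicit overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha1(canon.encode()).hexdigest()[:12]


def save_config(cfg: dict, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
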