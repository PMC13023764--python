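"""Run-configuration schema: a single YAML file with explicit units in
key names (``_mm``, ``_gy``, ``_kev``), validated with aggregated
errors and normalized by filling documented defaults."""

from __future__ import annotations

import copy

import yaml

__all__ = ["ConfigError", "validate_config", "load_config", "DEFAULT_CONFIG"]

DEFAULT_CONFIG = {
    "run": {
        "models": ["A", "B"],
        "kvp_list": [20, 40, 60, 80, 100, 120, 140, 160],
        "n_photons": 1_000_000,
        "n_batches": 10,
        "seed": 0,
        "voxel_size_mm": 0.2,
        "np_concentration_mg_ml": 10.0,
        "surface_dose_gy": 3.0,
        "coherent_scatter": True,
        "energy_cutoff_kev": 1.0,
    },
    "tube": {
        "bin_width_kev": 0.5,
        "min_energy_kev": 1.0,
        "filters": [["beryllium", 0.8]],
        "include_lines": True,
    },
    "cohort": {
        "enabled": True,
        "groups": ["control", 40, 80, 120, 160],
        "n_per_group": 5,
        "start_volume_range_mm3": [70.0, 125.0],
        "days": 14,
        "control_growth_rate_per_day": 0.20,
        "dose_effect_slope": 0.8,
        "noise_cv": 0.15,
    },
}

_REQUIRED = ("run.models", "run.kvp_list", "run.n_photons", "run.seed")


class ConfigError(ValueError):
    """Aggregated configuration problems."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" + "\n".join(f"- {e}" for e in self.errors))


def _merge_defaults(user: dict, defaults: dict, prefix: str, errors: list) -> dict:
    out = copy.deepcopy(defaults)
    for key, val in user.items():
        if key not in defaults:
            errors.append(f"unknown key {prefix}{key}")
            continue
        if isinstance(defaults[key], dict) and isinstance(val, dict):
            out[key] = _merge_defaults(val, defaults[key], f"{prefix}{key}.", errors)
        else:
            out[key] = val
    return out


def validate_config(raw: dict) -> dict:
    """Normalize a raw config dict; raises ConfigError listing every
    problem found (not first-fail).  Idempotent on its own output."""
    errors: list = []
    if not isinstance(raw, dict):
        raise ConfigError(["configuration must be a mapping; "
                           f"required keys include {', '.join(_REQUIRED)}"])
    cfg = _merge_defaults(raw, DEFAULT_CONFIG, "", errors)
    run = cfg["run"]
    for m in run["models"]:
        if str(m).upper() not in ("A", "B", "C", "D"):
            errors.append(f"run.models: unknown model {m!r}")
    run["models"] = [str(m).upper() for m in run["models"]]
    for k in run["kvp_list"]:
        if not (isinstance(k, (int, float)) and 10 <= k <= 200):
            errors.append(f"run.kvp_list: tube potential {k!r} outside [10, 200] kV")
    if not (isinstance(run["n_photons"], int) and run["n_photons"] > 0):
        errors.append(f"run.n_photons: need a positive integer, got {run['n_photons']!r}")
    if not (isinstance(run["n_batches"], int) and run["n_batches"] >= 2):
        errors.append("run.n_batches: need an integer >= 2")
    if not isinstance(run["seed"], int):
        errors.append("run.seed: need an integer")
    if not (0 < run["voxel_size_mm"] <= 5.0):
        errors.append("run.voxel_size_mm: must lie in (0, 5]")
    else:
        n = 5.0 / run["voxel_size_mm"]
        if abs(n - round(n)) > 1e-9:
            errors.append(f"run.voxel_size_mm: {run['voxel_size_mm']} does not divide the 5 mm tumor")
    if run["np_concentration_mg_ml"] < 0:
        errors.append("run.np_concentration_mg_ml: must be non-negative")
    if run["surface_dose_gy"] <= 0:
        errors.append("run.surface_dose_gy: must be positive")
    tube = cfg["tube"]
    if tube["bin_width_kev"] <= 0:
        errors.append("tube.bin_width_kev: must be positive")
    for f in tube["filters"]:
        if len(f) != 2 or f[1] < 0:
            errors.append(f"tube.filters: entry {f!r} must be [material, thickness_mm >= 0]")
    coh = cfg["cohort"]
    if coh["n_per_group"] < 1:
        errors.append("cohort.n_per_group: need at least 1")
    if coh["noise_cv"] < 0 or coh["dose_effect_slope"] < 0 or coh["control_growth_rate_per_day"] < 0:
        errors.append("cohort: rates, slope and noise must be non-negative")
    if errors:
        raise ConfigError(errors)
    return cfg


def load_config(path) -> dict:
    """Read and validate a YAML config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    return validate_config(raw)
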