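"""Flat key-value run configuration.

A run config is a flat mapping of scalar values (YAML on disk).  Keys
carry explicit units where time or information scales are involved
(``burn_in_sweeps``, ``epsilon_bits``) so the steps-versus-sweeps
ambiguity cannot creep into result files.  Every command writes back the
fully resolved config it actually used.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["DEFAULTS", "load_config", "save_config", "resolve_config"]

Scalar = int | float | str | bool | None

DEFAULTS: dict[str, Scalar] = {
    # network ensemble
    "n_units": 500,
    "gamma": 1.6,
    "k_min": 1,
    "k_max": None,  # floor(sqrt(n_units)) when None
    "max_retries": 100,
    # dynamics
    "temperature": 2.5,
    "coupling": 1.0,
    "rule": "glauber",
    "schedule": "random-site",
    "burn_in_sweeps": 1000,
    # analytic pipeline
    "epsilon_bits": 1e-3,
    "c_eff": 1.0,
    "neighbor_magnetization": "stationary",  # number, or the stationary fixed point
    # empirical pipeline
    "n_realizations": 6,
    "n_series": 5000,
    "tau_max_sweeps": 20,
    "empirical_epsilon_bits": 0.01,
    "n_prior_samples": 2000,
    "prior_stride_sweeps": 2,
    # bookkeeping
    "seed": 0,
    "trajectory_layout": "dense",  # or "long": (sweep, unit_id, state) rows
}


def load_config(path: str | Path) -> dict[str, Scalar]:
    """Read a flat YAML mapping; reject nested or unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    out: dict[str, Scalar] = {}
    for key, value in raw.items():
        if isinstance(value, (dict, list)):
            raise ValueError(f"{path}: key {key!r} is nested; config must be flat")
        if key not in DEFAULTS:
            raise ValueError(f"{path}: unknown config key {key!r}")
        out[str(key)] = value
    return out


def save_config(config: Mapping[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, default_flow_style=False, sort_keys=True)


def resolve_config(
    overrides: Mapping[str, Any] | None = None, **kwargs: Any
) -> dict[str, Scalar]:
    """Defaults, updated by a loaded config, updated by keyword overrides."""
    resolved = dict(DEFAULTS)
    for source in (overrides or {}, kwargs):
        for key, value in source.items():
            if key not in DEFAULTS:
                raise ValueError(f"unknown config key {key!r}")
            if value is not None or key == "k_max":
                resolved[key] = value
    return resolved
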