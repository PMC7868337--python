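"""Configuration loading.

The packaged default configuration encodes the four reference neonates, the
treatment windows, the published anchor concentrations and every model
constant.  A user configuration file (YAML) is deep-merged over the
defaults, so a file only needs the keys it overrides.
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError

_REQUIRED_TOP_LEVEL = ("model", "profiles", "periods", "anchors", "calibration", "cohort")
_REQUIRED_MODEL_KEYS = (
    "cl_bl_raw_l_day",
    "baseline_covariate_factor",
    "vd_per_kg_l",
    "ibuprofen_reduction_ml_min",
    "horizon_days",
    "step_days",
)


def default_config() -> dict[str, Any]:
    """Return a fresh copy of the packaged default configuration."""
    text = resources.files("neocrea.data").joinpath("default_config.yaml").read_text()
    return yaml.safe_load(text)


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load the effective configuration, merging ``path`` over the defaults.

    Raises
    ------
    ConfigError
        If the file cannot be parsed or a required key is missing.
    """
    cfg = default_config()
    if path is not None:
        p = Path(path)
        if not p.is_file():
            raise ConfigError(f"configuration file not found: {p}")
        try:
            user = yaml.safe_load(p.read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse configuration {p}: {exc}") from exc
        if user is None:
            user = {}
        if not isinstance(user, Mapping):
            raise ConfigError(f"configuration {p} must be a mapping at top level")
        cfg = _deep_merge(cfg, user)
    validate_config(cfg)
    return cfg


def validate_config(cfg: Mapping[str, Any]) -> None:
    """Check that every required key is present, naming any missing one."""
    missing = [k for k in _REQUIRED_TOP_LEVEL if k not in cfg]
    if missing:
        raise ConfigError(f"missing required configuration section(s): {missing}")
    missing_model = [k for k in _REQUIRED_MODEL_KEYS if k not in cfg["model"]]
    if missing_model:
        raise ConfigError(f"missing required model key(s): {missing_model}")
    if not cfg["profiles"]:
        raise ConfigError("configuration must define at least one profile")
    for i, prof in enumerate(cfg["profiles"]):
        for key in ("id", "gestational_age", "birth_weight_g", "initial_creatinine_mg_dl"):
            if key not in prof:
                raise ConfigError(f"profile #{i} missing required key: {key}")
    for i, per in enumerate(cfg["periods"]):
        for key in ("start_day", "duration_days", "doses_mg_per_kg"):
            if key not in per:
                raise ConfigError(f"period #{i} missing required key: {key}")
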