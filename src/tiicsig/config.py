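"""Pipeline configuration: defaults, YAML loading, light schema checks."""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigurationError

_KNOWN_KEYS = {
    "radii_um", "effective_density_radius_um", "signature_radius_um",
    "tertile_split", "score_cut", "response_models", "simulate",
}


def default_config() -> dict:
    with resources.files("tiicsig.data").joinpath("default_config.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_config(path: str | Path | None = None) -> dict:
    """Merge a user YAML over the shipped defaults and validate keys."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - _KNOWN_KEYS
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(cfg.get(key), dict):
                cfg[key] = {**cfg[key], **value}
            else:
                cfg[key] = value
    _validate(cfg)
    return cfg


def _validate(cfg: dict) -> None:
    if not all(r > 0 for r in cfg["radii_um"]):
        raise ConfigurationError("radii_um must be positive")
    rm = cfg["response_models"]
    if rm["folds"] < 2:
        raise ConfigurationError("response_models.folds must be >= 2")
    if rm["repetitions"] < 1 or rm["fast_repetitions"] < 1:
        raise ConfigurationError("repetition counts must be >= 1")
    bad = [f for f in rm["families"] if f not in ("etc", "gbc", "abc", "mlp")]
    if bad:
        raise ConfigurationError(f"unknown classifier families: {bad}")


def config_hash(cfg: dict) -> str:
    """Stable hash of the canonicalised configuration."""
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
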