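"""Configuration loading and validation.

Configs are flat YAML/JSON mappings whose keys are exactly the
:class:`~somasim.lattice.SimConfig` field names. Validation is
aggregated: every out-of-range value and every unknown key is reported
in a single error rather than failing on the first problem. An empty
config yields all defaults.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from somasim.lattice import SimConfig

__all__ = ["ConfigError", "validate_config", "load_config", "config_hash"]


class ConfigError(ValueError):
    """Aggregated, human-readable configuration errors."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.errors))


_FIELDS = {f.name: f for f in dataclasses.fields(SimConfig)}

_UNIT_FIELDS = {
    "a",
    "seed_density",
    "stem_competition",
    "somatic_boost",
    "beta_soma",
    "soma_resistance",
    "p_somatic",
}


def validate_config(raw: dict | None) -> SimConfig:
    """Range-check a raw mapping and return a typed :class:`SimConfig`.

    Unknown keys are rejected by name; all problems are aggregated into
    one :class:`ConfigError`.
    """
    raw = dict(raw or {})
    errors: list[str] = []

    unknown = sorted(set(raw) - set(_FIELDS))
    if unknown:
        errors.append(f"unknown keys: {', '.join(unknown)}")
        for key in unknown:
            raw.pop(key)

    for key in _UNIT_FIELDS & set(raw):
        v = raw[key]
        if not isinstance(v, (int, float)) or not 0.0 <= float(v) <= 1.0:
            errors.append(f"{key} must be a number in [0, 1], got {v!r}")
            raw.pop(key)
    for key in ("rows", "cols", "cycles", "rng_seed"):
        if key in raw and not isinstance(raw[key], int):
            errors.append(f"{key} must be an integer, got {raw[key]!r}")
            raw.pop(key)

    try:
        config = SimConfig(**raw)
    except (TypeError, ValueError) as exc:
        errors.append(str(exc))
        raise ConfigError(errors) from exc
    if errors:
        raise ConfigError(errors)
    return config


def load_config(path: str | Path) -> SimConfig:
    """Load and validate a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError([f"config root must be a mapping, got {type(raw).__name__}"])
    return validate_config(raw)


def config_hash(config: SimConfig) -> str:
    """Stable short hash of the full parameterization, for manifests."""
    import hashlib

    payload = json.dumps(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
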