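"""Run configuration: schema validation, defaults resolution, provenance."""

from __future__ import annotations

import difflib
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import params

_SIM_KEYS = {"state", "scale", "duration", "dt", "seed", "out_of_field",
             "weight_rescale_cap", "record", "output"}
_TOP_KEYS = {"simulation", "cells", "reversals", "synapse_classes",
             "populations", "generators", "generators_override",
             "connections", "gap_junctions", "tonic_currents", "lfp", "bands"}


class ConfigError(ValueError):
    """Carries every violation found during validation."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("invalid run config:\n  - " + "\n  - ".join(self.violations))


@dataclass
class RunConfig:
    """A fully resolved configuration (defaults merged with overrides)."""

    resolved: dict
    seed: int = 0
    source_path: str | None = None

    @property
    def simulation(self) -> dict:
        return self.resolved["simulation"]

    @property
    def bands(self) -> dict:
        return self.resolved["bands"]

    @property
    def config_hash(self) -> str:
        text = json.dumps(self.resolved, sort_keys=True, default=float)
        return hashlib.sha256(text.encode()).hexdigest()


def _suggest(key: str, valid) -> str:
    close = difflib.get_close_matches(key, list(valid), n=1)
    hint = f" (did you mean {close[0]!r}?)" if close else ""
    return f"unknown key {key!r}{hint}"


def validate(overrides: dict) -> list[str]:
    """All schema violations in an override map (empty list = valid)."""
    errors = []
    defaults = params.defaults()
    for key in overrides:
        if key not in _TOP_KEYS:
            errors.append(_suggest(key, _TOP_KEYS))
    sim = overrides.get("simulation", {})
    if not isinstance(sim, dict):
        errors.append("simulation section must be a mapping")
        sim = {}
    for key in sim:
        if key not in _SIM_KEYS:
            errors.append("simulation: " + _suggest(key, _SIM_KEYS))
    state = sim.get("state", "theta")
    if state not in ("theta", "non_theta"):
        errors.append(f"simulation.state must be theta|non_theta, got {state!r}")
    scale = sim.get("scale", 1.0)
    try:
        if not 0 < float(scale) <= 1:
            errors.append(f"simulation.scale must lie in (0, 1], got {scale}")
    except (TypeError, ValueError):
        errors.append(f"simulation.scale must be a number, got {scale!r}")
    for key in ("duration", "dt"):
        if key in sim:
            try:
                if float(sim[key]) <= 0:
                    errors.append(f"simulation.{key} must be positive")
            except (TypeError, ValueError):
                errors.append(f"simulation.{key} must be a number")
    for name, band in overrides.get("bands", {}).items():
        if name not in defaults["bands"]:
            errors.append("bands: " + _suggest(name, defaults["bands"]))
            continue
        try:
            lo, hi = float(band[0]), float(band[1])
            if not 0 < lo < hi:
                errors.append(f"bands.{name}: need 0 < low < high, got {band}")
        except (TypeError, ValueError, IndexError):
            errors.append(f"bands.{name}: expected (low, high) Hz, got {band!r}")
    for name in overrides.get("populations", {}):
        if name not in defaults["populations"]:
            errors.append("populations: " + _suggest(name, defaults["populations"]))
    for name in overrides.get("tonic_currents", {}):
        if name not in ("background", "cholinergic"):
            errors.append("tonic_currents: "
                          + _suggest(name, ("background", "cholinergic")))
    return errors


def resolve(overrides: dict | None = None, seed: int = 0,
            source_path: str | None = None) -> RunConfig:
    """Validate overrides and merge them into the defaults."""
    overrides = overrides or {}
    errors = validate(overrides)
    if errors:
        raise ConfigError(errors)
    resolved = params.deep_merge(params.defaults(), overrides)
    if "seed" in resolved.get("simulation", {}):
        seed = int(resolved["simulation"]["seed"])
    return RunConfig(resolved=resolved, seed=seed, source_path=source_path)


def load_and_validate(path) -> RunConfig:
    """Load a YAML/JSON run config file and resolve it against the defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    data = (json.loads(text) if path.suffix.lower() == ".json"
            else yaml.safe_load(text)) or {}
    if not isinstance(data, dict):
        raise ConfigError([f"config root must be a mapping, got {type(data).__name__}"])
    return resolve(data, source_path=str(path))
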