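"""Structured plain-text (YAML) configuration.

A run configuration bundles the five parameter groups; every key is
optional and defaults to the baseline farm values.  Unknown sections or
keys are rejected with the offending name, so typos never silently fall
back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

from .params import (EconParams, LifeHistory, OperatingTargets, Policy,
                     StochasticConfig, StockConfig)

__all__ = ["ConfigError", "RunConfig", "load_config", "dump_config"]


class ConfigError(ValueError):
    """Malformed or unknown configuration content."""


_SECTIONS = {
    "life_history": LifeHistory,
    "stock": StockConfig,
    "policy": Policy,
    "targets": OperatingTargets,
    "economics": EconParams,
    "stochastic": StochasticConfig,
}


@dataclass(frozen=True)
class RunConfig:
    life_history: LifeHistory = LifeHistory()
    stock: StockConfig = StockConfig()
    policy: Policy = Policy()
    targets: OperatingTargets = OperatingTargets()
    economics: EconParams = EconParams()
    stochastic: StochasticConfig = StochasticConfig()


def _build_section(cls, name: str, data: Any):
    if data is None:
        return cls()
    if not isinstance(data, dict):
        raise ConfigError(f"section '{name}' must be a mapping")
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section '{name}': {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}")
    fixed = dict(data)
    if cls is StochasticConfig and "clutch_bounds" in fixed:
        fixed["clutch_bounds"] = tuple(fixed["clutch_bounds"])
    try:
        return cls(**fixed)
    except ValueError as err:
        raise ConfigError(f"section '{name}': {err}") from err


def from_dict(data: dict[str, Any] | None) -> RunConfig:
    """Build a validated RunConfig from a nested mapping."""
    data = data or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown section(s): {sorted(unknown)}; "
                          f"allowed: {sorted(_SECTIONS)}")
    return RunConfig(**{name: _build_section(cls, name, data.get(name))
                        for name, cls in _SECTIONS.items()})


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML configuration file; ``None`` gives all defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as err:
        raise ConfigError(f"cannot parse {path}: {err}") from err
    return from_dict(data)


def to_dict(rc: RunConfig) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        section = dataclasses.asdict(getattr(rc, name))
        if "clutch_bounds" in section:
            section["clutch_bounds"] = list(section["clutch_bounds"])
        out[name] = section
    return out


def dump_config(rc: RunConfig, path: str | Path | None = None) -> str:
    """Serialise a RunConfig to YAML; round-trips through load_config."""
    text = yaml.safe_dump(to_dict(rc), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
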