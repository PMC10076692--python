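"""Run configuration: every tunable design parameter in one YAML-able object.

A written config re-read reproduces itself exactly; unknown keys are
rejected with the offending section and key named.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .factor import FactorConfig
from .grip import GripConfig


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ConnectomeConfig:
    alpha: float = 1.0  # distance exponent of the correction
    beta: float = 1.0  # summed-volume exponent


@dataclass(frozen=True)
class AssociationConfig:
    edge_weight_threshold: float = 0.4  # |composite weight| cut for reported edges
    top_edges: int = 6
    vif_warn: float = 10.0
    lesion_membership: str = "continuous"  # or "thresholded"
    composite_combine: str = "max_abs"  # or "sum"


@dataclass(frozen=True)
class RunConfig:
    grip: GripConfig = field(default_factory=GripConfig)
    connectome: ConnectomeConfig = field(default_factory=ConnectomeConfig)
    factor: FactorConfig = field(default_factory=FactorConfig)
    association: AssociationConfig = field(default_factory=AssociationConfig)
    seed: int = 0


_SECTIONS = {
    "grip": GripConfig,
    "connectome": ConnectomeConfig,
    "factor": FactorConfig,
    "association": AssociationConfig,
}


def _build_section(name: str, cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown key(s) in section {name!r}: {unknown}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        coerced[f.name] = v
    return cls(**coerced)


def config_to_dict(config: RunConfig) -> dict:
    out: dict = {}
    for name, cls in _SECTIONS.items():
        out[name] = dataclasses.asdict(getattr(config, name))
    out["seed"] = config.seed
    return out


def config_from_dict(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError(f"config must be a mapping, got {type(data).__name__}")
    unknown = sorted(set(data) - set(_SECTIONS) - {"seed"})
    if unknown:
        raise ConfigError(f"unknown top-level config key(s): {unknown}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = data.get(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        kwargs[name] = _build_section(name, cls, section)
    seed = data.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError(f"seed must be an integer, got {seed!r}")
    return RunConfig(seed=seed, **kwargs)


def write_config(config: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def read_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    try:
        return config_from_dict(data)
    except ConfigError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
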