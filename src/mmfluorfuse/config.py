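"""Run configuration: YAML loading, validation, seed fan-out, hashing.

A single global seed fans out into named sub-seeds (generate / split /
jitter / init / train) so each pipeline stage is independently
reproducible.  Unknown YAML keys are rejected by name; nested sections
map onto the generator/model/training dataclasses and inherit their
invariants.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields

import yaml

from .errors import ConfigError
from .model import ModelConfig
from .synthetic import GeneratorConfig
from .training import TrainConfig


def derive_seed(master: int, name: str) -> int:
    """Deterministic named sub-seed below 2**31."""
    h = hashlib.sha256(f"{master}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    seed: int = 0
    workdir: str = "runs/default"
    crop_side: int = 664
    jitter_lo: float = 0.001
    jitter_hi: float = 0.009
    split_ratios: tuple = (0.8, 0.1, 0.1)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self):
        self.split_ratios = tuple(self.split_ratios)
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ConfigError(f"split_ratios must sum to 1, got {self.split_ratios}")
        if self.crop_side < 1:
            raise ConfigError("crop_side must be positive")
        if not 0 <= self.jitter_lo <= self.jitter_hi:
            raise ConfigError("need 0 <= jitter_lo <= jitter_hi")


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"section {path or 'root'} must be a mapping")
    valid = {f.name: f for f in fields(cls)}
    unknown = [k for k in data if k not in valid]
    if unknown:
        raise ConfigError(f"unknown config key(s) {unknown} in {path or 'root'}")
    kwargs = {}
    for name, value in data.items():
        ftype = valid[name].type
        sub = {"generator": GeneratorConfig, "model": ModelConfig,
               "train": TrainConfig}.get(name)
        if sub is not None:
            kwargs[name] = _build(sub, value or {}, f"{path}{name}.")
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid configuration in {path or 'root'}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (empty file = defaults)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return _build(RunConfig, data or {}, "")


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=False)
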