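"""Declarative pipeline configuration: nested sections mirroring each stage.

A single YAML file (all keys optional, unknown keys rejected) configures the
whole pipeline; every field has a default, so the end-to-end run works with no
arguments.  The config round-trips losslessly through ``to_dict``/``from_dict``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError
from .features import STFTConfig, WindowSpec
from .model import ModelConfig
from .simulate import SimConfig
from .traineval import SplitSpec, TrainConfig

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PreprocessConfig:
    bandpass_low_hz: float = 20.0
    bandpass_high_hz: float = 300.0
    bandstop_low_hz: float = 49.0
    bandstop_high_hz: float = 51.0
    filter_order: int = 2
    zero_phase: bool = True
    pressure_smooth_s: float = 0.02
    pressure_threshold: float = 0.5
    min_phase_s: float = 0.05


@dataclass
class PipelineConfig:
    simulate: SimConfig = field(default_factory=SimConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    window: WindowSpec = field(default_factory=WindowSpec)
    stft: STFTConfig = field(default_factory=STFTConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Propagate one global seed to every seeded stage."""
        seed = int(seed)
        return dataclasses.replace(
            self,
            seed=seed,
            simulate=dataclasses.replace(self.simulate, seed=seed),
            split=dataclasses.replace(self.split, seed=seed),
            train=dataclasses.replace(self.train, seed=seed),
        )

    def to_dict(self) -> dict:
        return _as_plain(dataclasses.asdict(self))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        cfg = cls()
        sections = {f.name: f for f in dataclasses.fields(cls)}
        updates: dict = {}
        for key, value in (data or {}).items():
            if key not in sections:
                raise ConfigurationError(f"unknown config section {key!r}")
            if key == "seed":
                updates["seed"] = int(value)
                continue
            section_obj = getattr(cfg, key)
            valid = {f.name for f in dataclasses.fields(section_obj)}
            unknown = set(value) - valid
            if unknown:
                raise ConfigurationError(
                    f"unknown keys in section {key!r}: {sorted(unknown)}"
                )
            coerced = {k: _coerce(section_obj, k, v) for k, v in value.items()}
            updates[key] = dataclasses.replace(section_obj, **coerced)
        return dataclasses.replace(cfg, **updates)


def _coerce(section_obj, name: str, value):
    current = getattr(section_obj, name)
    if isinstance(current, np.ndarray):
        return np.asarray(value, dtype=float)
    if isinstance(current, tuple):
        return tuple(tuple(v) if isinstance(v, (list, tuple)) else v for v in value)
    return value


def _as_plain(obj):
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config file; ``None`` gives all defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError("config file must contain a mapping")
    return PipelineConfig.from_dict(data)
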