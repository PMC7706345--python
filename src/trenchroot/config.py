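"""YAML pipeline configuration: parse-validate before any stage runs.

One file describes every stage (frame, synth, augment, model, train)
plus paths and the master seed.  Unknown keys are rejected so typos
fail fast instead of silently using defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .augment import AugmentConfig
from .raster_io import FrameSpec
from .segmenter import ModelConfig, TrainConfig
from .synth import SynthConfig

__all__ = ["PipelineConfig", "load_config", "config_hash"]


def _build(cls, block: dict, name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown keys in '{name}' block: {sorted(unknown)}")
    fixed = {}
    for k, v in block.items():
        fixed[k] = tuple(v) if isinstance(v, list) else v
    return cls(**fixed)


@dataclass
class PipelineConfig:
    frame: FrameSpec = field(default_factory=FrameSpec)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    seed: int = 0
    workdir: Path = Path(".")


_BLOCKS = {"frame": FrameSpec, "augment": AugmentConfig, "model": ModelConfig,
           "train": TrainConfig, "synth": SynthConfig}


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(_BLOCKS) - {"seed", "workdir"}
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs = {name: _build(cls, raw.get(name, {}) or {}, name)
              for name, cls in _BLOCKS.items()}
    cfg = PipelineConfig(**kwargs, seed=int(raw.get("seed", 0)),
                         workdir=Path(raw.get("workdir", ".")))
    return cfg


def config_hash(cfg: PipelineConfig) -> str:
    """Short stable digest of the full configuration, for provenance
    comments in emitted CSVs."""
    def enc(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)
    blob = json.dumps({f.name: enc(getattr(cfg, f.name))
                       for f in dataclasses.fields(cfg)}, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
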