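"""Flat YAML config files for the simulation and pipeline stages.

Keys match the dataclass field names one-to-one; unknown keys raise so
typos do not silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .pipeline import PipelineConfig
from .synthetic import SimulationConfig


def _load(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        obj = yaml.safe_load(fh) or {}
    if not isinstance(obj, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return obj


def _build(cls, obj: dict, overrides: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    merged = {**obj, **overrides}
    unknown = set(merged) - fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    # YAML has no tuple type; coerce list-valued fields
    for key, value in merged.items():
        if isinstance(value, list):
            merged[key] = tuple(value)
    return cls(**merged)


def load_simulation_config(path: str | Path, **overrides) -> SimulationConfig:
    cfg = _build(SimulationConfig, _load(path), overrides)
    cfg.validate()
    return cfg


def load_pipeline_config(path: str | Path, **overrides) -> PipelineConfig:
    return _build(PipelineConfig, _load(path), overrides)


def save_config(config, path: str | Path) -> None:
    obj = dataclasses.asdict(config)
    for key, value in obj.items():
        if isinstance(value, tuple):
            obj[key] = list(value)
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))
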