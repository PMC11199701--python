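"""YAML pipeline configuration with strict schema validation.

Unknown keys are rejected so typos fail fast rather than silently falling
back to defaults.
"""

from __future__ import annotations

from dataclasses import fields, is_dataclass
from pathlib import Path
from typing import Any

import yaml

from .features import MetricRegistry, SpectralConfig
from .io import LabelConfig
from .modeling import CVConfig
from .preprocessing import SegmentationConfig, SmoothingConfig
from .simulate import ArtifactSpec, SeverityEffects, SyntheticCohortConfig

__all__ = ["PipelineConfig", "load_config", "ConfigError"]

_BLOCKS = {
    "smoothing": SmoothingConfig,
    "segmentation": SegmentationConfig,
    "labels": LabelConfig,
    "metrics": MetricRegistry,
    "spectral": SpectralConfig,
    "modeling": CVConfig,
    "simulate": SyntheticCohortConfig,
}

_TOP_LEVEL = set(_BLOCKS) | {"seed", "out_dir", "log_level"}


class ConfigError(ValueError):
    pass


def _build(cls, data: dict[str, Any], path: str):
    if not is_dataclass(cls):
        raise ConfigError(f"{path}: not a config block")
    allowed = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(allowed)
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        sub = {"effects": SeverityEffects, "artifacts": ArtifactSpec}.get(key)
        if sub is not None and isinstance(value, dict):
            value = _build(sub, value, f"{path}.{key}")
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


class PipelineConfig:
    """Parsed pipeline YAML: one attribute per block, defaults elsewhere."""

    def __init__(self, raw: dict[str, Any]):
        unknown = set(raw) - _TOP_LEVEL
        if unknown:
            raise ConfigError(f"unknown top-level keys {sorted(unknown)}")
        self.seed = int(raw.get("seed", 0))
        self.out_dir = Path(raw.get("out_dir", "kinemetrix_out"))
        self.log_level = str(raw.get("log_level", "INFO"))
        for name, cls in _BLOCKS.items():
            block = raw.get(name, {}) or {}
            if not isinstance(block, dict):
                raise ConfigError(f"{name}: expected a mapping")
            setattr(self, name, _build(cls, block, name))


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig({})
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return PipelineConfig(raw)
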