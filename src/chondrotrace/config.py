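"""Pipeline configuration: nested parameter sections with strict loading.

A configuration round-trips losslessly through YAML/JSON; unknown keys are
rejected so a typo never silently falls back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .classify import TreeParams
from .features import PeakParams, StepParams
from .intensity import BackgroundParams
from .synth import MotionModel, RenderParams, ScenarioParams
from .tracking import TrackParams


class ConfigError(ValueError):
    pass


@dataclass
class SpatialConfig:
    bin_size: float = 64.0
    reference_frame: int | None = None  # default: first static frame


@dataclass
class PipelineConfig:
    """All stage parameters plus the global seed and smoothing window."""

    scenario: ScenarioParams = field(default_factory=ScenarioParams)
    render: RenderParams = field(default_factory=RenderParams)
    tracking: TrackParams = field(default_factory=TrackParams)
    background: BackgroundParams = field(default_factory=BackgroundParams)
    peaks: PeakParams = field(default_factory=PeakParams)
    steps: StepParams = field(default_factory=StepParams)
    tree: TreeParams = field(default_factory=TreeParams)
    spatial: SpatialConfig = field(default_factory=SpatialConfig)
    smooth_window: int = 20
    #: tracks with fewer detected frames are dropped before trace
    #: extraction (spurious detections form short fragments, not cells)
    min_detected_frames: int = 50
    seed: int = 0

    def validate(self) -> None:
        """Cross-section checks that must fail before any compute."""
        field_size = self.scenario.field_size
        base = field_size // self.background.grid
        if base == 0:
            raise ConfigError("background grid finer than the image")
        if self.background.n_lowest > base * base:
            raise ConfigError(
                f"background.n_lowest={self.background.n_lowest} exceeds the "
                f"{base * base} pixels of a grid region"
            )
        if self.smooth_window < 1:
            raise ConfigError("smooth_window must be >= 1")


_SECTIONS = {
    "scenario": ScenarioParams,
    "render": RenderParams,
    "tracking": TrackParams,
    "background": BackgroundParams,
    "peaks": PeakParams,
    "steps": StepParams,
    "tree": TreeParams,
    "spatial": SpatialConfig,
}


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping")
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if f.name == "motion" and isinstance(v, dict):
            v = _build(MotionModel, v, f"{path}.motion")
        if f.name == "category_weights" and v is not None:
            v = tuple(v)
        if f.name == "impact_center" and v is not None:
            v = tuple(v)
        if f.name == "background_offsets" and v is not None:
            v = np.asarray(v, dtype=float)
        kwargs[f.name] = v
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def config_from_dict(data: dict) -> PipelineConfig:
    if not isinstance(data, dict):
        raise ConfigError("top level: expected a mapping")
    unknown = set(data) - set(_SECTIONS) - {"smooth_window", "min_detected_frames", "seed"}
    if unknown:
        raise ConfigError(f"top level: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _build(cls, data[name], name)
    for scalar in ("smooth_window", "min_detected_frames", "seed"):
        if scalar in data:
            kwargs[scalar] = int(data[scalar])
    cfg = PipelineConfig(**kwargs)
    cfg.validate()
    return cfg


def config_to_dict(cfg: PipelineConfig) -> dict:
    def clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: clean(getattr(obj, f.name)) for f in fields(obj)}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (tuple, list)):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        return obj

    return clean(cfg)


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text())
    return config_from_dict(data or {})


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))
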