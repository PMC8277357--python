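"""Run configuration: schema, defaults, and YAML/JSON loading.

The schema is a tree of frozen dataclasses whose field defaults are the
engine defaults documented in docs/methods.md. Loading is strict: unknown
keys anywhere in the tree are rejected rather than ignored, so typos cannot
silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError


@dataclass(frozen=True)
class EstimatorConfig:
    """Welch estimator and streaming-window settings."""

    window_s: float = 2.0
    step_s: float = 0.5
    taper: str = "hann"
    overlap: float = 0.5
    artifact_ptp_uv: float = 200.0


@dataclass(frozen=True)
class FeedbackConfig:
    """Feedback formula choice, scaling constants, and smoothing."""

    formula: str = "new"  # {"new", "original"}: which index drives the game
    k_beta: float = 1.0
    k_alpha: float = 1.0
    k_alpha_low: float = 1.0
    k_alpha_high: float = 1.0
    k_theta: float = 1.0
    ema_alpha: float = 0.4

    def __post_init__(self) -> None:
        if self.formula not in ("new", "original"):
            raise ConfigError(f"formula must be 'new' or 'original', got {self.formula!r}")


@dataclass(frozen=True)
class ControllerConfig:
    """Threshold placement and adaptation policy."""

    fraction: float = 1.0 / 3.0
    adapt_rate: float = 0.2
    adapt_horizon_s: float = 15.0
    adapt_every_s: float = 1.0
    policy: str = "recenter"
    calibration_s: float = 30.0


@dataclass(frozen=True)
class GameConfig:
    """Abstract game defaults."""

    game_id: str = "run_run"
    dv: float = 0.2
    tick_s: float = 0.5
    game_minutes: float = 2.5
    break_minutes: float = 1.0
    shoot_escalation: float = 0.05


@dataclass(frozen=True)
class SynthConfig:
    """Synthetic-stream defaults for sessions run without hardware."""

    fs: float = 250.0
    noise_scale: float = 1.0
    one_over_f_exponent: float = 1.0
    game_duration_s: float = 150.0


@dataclass(frozen=True)
class AnalysisConfig:
    """Offline pre/post analysis options."""

    log_scale: bool = True
    alpha: float = 0.05


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration; `seed` feeds every random substream."""

    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    feedback: FeedbackConfig = field(default_factory=FeedbackConfig)
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    game: GameConfig = field(default_factory=GameConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0


def _from_dict(cls: type, data: dict[str, Any], path: str) -> Any:
    if not isinstance(data, dict):
        raise ConfigError(f"{path or 'config'}: expected a mapping, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"unknown config key(s) at {path or 'top level'}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        target = _SECTION_TYPES.get((cls, name))
        kwargs[name] = _from_dict(target, value, f"{path}.{name}" if path else name) if target else value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config at {path or 'top level'}: {exc}") from exc


_SECTION_TYPES = {
    (RunConfig, "estimator"): EstimatorConfig,
    (RunConfig, "feedback"): FeedbackConfig,
    (RunConfig, "controller"): ControllerConfig,
    (RunConfig, "game"): GameConfig,
    (RunConfig, "synth"): SynthConfig,
    (RunConfig, "analysis"): AnalysisConfig,
}


def config_from_dict(data: dict[str, Any]) -> RunConfig:
    """Build a RunConfig from a nested dict, rejecting unknown keys."""
    return _from_dict(RunConfig, data, "")


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    return config_from_dict(data)


def config_to_dict(cfg: RunConfig) -> dict[str, Any]:
    return dataclasses.asdict(cfg)
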