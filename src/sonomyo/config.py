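"""Validated pipeline configuration with the acquisition-system defaults."""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["PipelineConfig", "load_config", "save_config"]


class PipelineConfig(BaseModel):
    """All tunable pipeline settings; unknown keys are rejected.

    Defaults reflect the wearable acquisition system: 50 MHz sampling,
    1540 m/s speed of sound, 80 mm recorded depth, 90 Hz frame rate, 1.5 Hz
    tracker-fusion cutoff, 2.5 mm x 0.05 s brightness smoothing box, and a
    5 Hz fourth-order zero-lag Butterworth for joint traces (10 Hz is the
    usual choice for locomotion data).
    """

    model_config = ConfigDict(extra="forbid")

    sampling_frequency: float = Field(default=50e6, gt=0)
    frame_rate: float = Field(default=90.0, gt=0)
    speed_of_sound: float = Field(default=1540.0, gt=0)
    max_depth_mm: float = Field(default=80.0, gt=0)

    window_min_mm: float = Field(default=20.0, ge=0)
    window_max_mm: float = Field(default=50.0, gt=0)
    superficial_depth_mm: float = Field(default=5.0, ge=0)
    fusion_cutoff_hz: float = Field(default=1.5, gt=0)
    box_depth_mm: float = Field(default=2.5, gt=0)
    box_time_s: float = Field(default=0.05, gt=0)

    lowpass_cutoff_hz: float = Field(default=5.0, gt=0)
    lowpass_order: int = Field(default=4, ge=1)
    gait_min_cycle_s: float = Field(default=0.4, gt=0)
    gait_prominence_frac: float = Field(default=0.2, ge=0, lt=1)
    n_normalized_points: int = Field(default=101, ge=2)

    model_inputs: list[str] = Field(default=["thickness_mm", "angle_deg"])
    seed: int = 0


def load_config(path) -> PipelineConfig:
    """Load a JSON or YAML config; an empty file yields all defaults.

    Schema violations raise pydantic's validation error, which lists the
    offending keys.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return PipelineConfig(**data)


def save_config(path, config: PipelineConfig) -> None:
    Path(path).write_text(json.dumps(config.model_dump(), indent=2))
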