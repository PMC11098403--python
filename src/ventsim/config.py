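"""Run configuration: one validated object covering ventilator settings,
the simulated plant, and run/recording parameters.

Keys carry explicit unit suffixes (``ti_ms``, ``flow_lpm``,
``compliance_ml_per_cmh2o``) and unknown keys are rejected, so a typo or a
unit mix-up fails loudly before any simulation starts.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .controller import VentSettings
from .core import LungParams
from .gas_exchange import SubjectParams
from .pneumatics import CircuitParams

__all__ = ["RunConfig", "load_config", "config_echo"]


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    settings: VentSettings = Field(default_factory=VentSettings)
    lung: LungParams = Field(default_factory=LungParams)
    circuit: CircuitParams = Field(default_factory=CircuitParams)
    subject: Optional[SubjectParams] = None
    duration_s: float = 60.0
    dt_s: float = 0.001
    sample_interval_s: float = 0.01
    seed: Optional[int] = None

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if not 0 < self.dt_s <= 0.002:
            raise ValueError("dt_s must be in (0, 0.002] s")
        if self.sample_interval_s < self.dt_s:
            raise ValueError("sample_interval_s must be >= dt_s")
        noisy = (
            self.circuit.sensor_noise_sd_cmh2o > 0
            or self.circuit.flow_noise_sd_lpm > 0
        )
        if noisy and self.seed is None:
            raise ValueError("seed is mandatory when any sensor noise sd > 0")
        return self


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Every default is made explicit in the validated object (see
    :func:`config_echo`); validation errors name the offending field.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return RunConfig(**data)


def config_echo(config: RunConfig) -> str:
    """Canonical one-line JSON echo of the fully-defaulted configuration,
    embedded in every output file so a run can be reproduced exactly."""
    return json.dumps(config.model_dump(), sort_keys=True)
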