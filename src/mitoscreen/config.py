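"""Run configuration: schema-validated YAML/JSON, defaults = canonical values.

Every default equals the canonical study conditions, so ``mitoscreen full
--seed 1`` reproduces the packaged analysis without a config file.  The
baseline window must be stated explicitly in config files (it is an
experiment-design fact), but the canonical (-300, 0) s is used when no config
file is given.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, ValidationError


class SimulateBlock(BaseModel):
    conditions: list[str] = ["baseline", "lps", "lps_emapunil", "emapunil_only"]
    n_per_group: int = Field(10, ge=2)
    n_neurons: int = Field(10, ge=0)
    response_cv: float = Field(0.25, ge=0)
    frame_interval: float = Field(1.0, gt=0)
    duration: float = Field(2100.0, gt=0)
    treatment_time: float = Field(300.0, ge=300.0)


class KineticsBlock(BaseModel):
    baseline_window: tuple[float, float] = (-300.0, 0.0)
    rate_threshold: float = Field(0.25, gt=0)
    min_state_dur: float = Field(60.0, gt=0)
    min_plateau_dur: float = Field(45.0, gt=0)
    max_states: int = Field(3, ge=1)
    smooth_window: float = Field(30.0, gt=0)


class ReportBlock(BaseModel):
    control: str = "lps"
    treatment: str = "lps_emapunil"
    alpha: float = Field(0.05, gt=0, lt=1)
    adjust: bool = False


class RunConfig(BaseModel):
    mode: Literal["simulate", "analyze", "full"] = "full"
    seed: int = 1
    out: str = "mitoscreen_run"
    traces: Optional[str] = None
    simulate: SimulateBlock = SimulateBlock()
    kinetics: KineticsBlock = KineticsBlock()
    report: ReportBlock = ReportBlock()


class ConfigError(ValueError):
    """Config file violates the schema; message lists the offending fields."""


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load and validate a YAML/JSON config file, applying overrides.

    Config files must state ``kinetics.baseline_window`` explicitly; schema
    violations raise :class:`ConfigError` naming each offending field path.
    """
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        if "baseline_window" not in data.get("kinetics", {}):
            raise ConfigError("config missing required field: kinetics.baseline_window")
    for key, val in overrides.items():
        if val is not None:
            data[key] = val
    try:
        return RunConfig.model_validate(data)
    except ValidationError as err:
        paths = "; ".join(
            ".".join(str(p) for p in e["loc"]) + f": {e['msg']}" for e in err.errors()
        )
        raise ConfigError(f"invalid config: {paths}") from err
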