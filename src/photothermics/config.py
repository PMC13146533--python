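"""Validated run configuration (YAML), including the power-density → watts
conversion: laser instruments report W/cm², the energy balance needs watts,
so the config carries the illuminated beam area (default 1 cm²)."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .exceptions import ConfigError
from .thermal import LaserProtocol, LaserSegment, ThermalSystem

__all__ = ["SegmentConfig", "RunConfig", "load_config"]


class SegmentConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    start_s: float
    end_s: float
    power_W: float = Field(ge=0)


class RunConfig(BaseModel):
    """One structured config file, fully validated before any computation."""

    model_config = ConfigDict(extra="forbid")

    beam_area_cm2: float = Field(default=1.0, gt=0)
    power_density_W_per_cm2: Optional[float] = Field(default=None, gt=0)
    heat_capacity_total_J_per_K: Optional[float] = Field(default=None, gt=0)
    hA_W_per_K: Optional[float] = Field(default=None, gt=0)
    eta: Optional[float] = Field(default=None, ge=0, le=1)
    absorbance: Optional[float] = Field(default=None, ge=0)
    solvent_heat_W: float = Field(default=0.0, ge=0)
    ambient_temp_C: Optional[float] = None
    initial_temp_C: Optional[float] = None
    theta_floor: float = Field(default=0.05, ge=0, lt=1)
    plateau_k: int = Field(default=3, ge=1)
    through_origin: bool = False
    loading_mode: Literal["direct", "indirect"] = "indirect"
    laser_off_s: Optional[float] = Field(default=None, gt=0)
    protocol: list[SegmentConfig] = Field(default_factory=list)
    sampling_interval_s: float = Field(default=60.0, gt=0)
    noise_sigma_K: float = Field(default=0.0, ge=0)
    bleaching_per_cycle: float = Field(default=0.0, ge=0, lt=1)

    @property
    def laser_power_W(self) -> float:
        if self.power_density_W_per_cm2 is None:
            raise ConfigError("power_density_W_per_cm2 is required for this command")
        return self.power_density_W_per_cm2 * self.beam_area_cm2

    def thermal_system(self) -> ThermalSystem:
        missing = [
            name
            for name, v in [
                ("heat_capacity_total_J_per_K", self.heat_capacity_total_J_per_K),
                ("hA_W_per_K", self.hA_W_per_K),
                ("eta", self.eta),
                ("absorbance", self.absorbance),
            ]
            if v is None
        ]
        if missing:
            raise ConfigError(f"config lacks fields required to build a system: {missing}")
        if self.ambient_temp_C is None:
            raise ConfigError("ambient_temp_C is required to build a system")
        return ThermalSystem(
            heat_capacity_total=self.heat_capacity_total_J_per_K,
            hA=self.hA_W_per_K,
            eta=self.eta,
            absorbance=self.absorbance,
            solvent_heat=self.solvent_heat_W,
            ambient_temp=self.ambient_temp_C,
        )

    def laser_protocol(self) -> LaserProtocol:
        if not self.protocol:
            raise ConfigError("config lists no protocol segments")
        return LaserProtocol(
            [LaserSegment(s.start_s, s.end_s, s.power_W) for s in self.protocol]
        )


def load_config(path) -> RunConfig:
    """Read and validate a YAML run configuration; unknown keys are rejected."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    try:
        raw = yaml.safe_load(p.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {p}: {exc}") from exc
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(f"invalid config {p}: {exc}") from exc
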