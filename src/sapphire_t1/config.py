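"""Run-configuration schema (YAML) for reproducible simulate/fit/report runs."""

from __future__ import annotations

import hashlib
import json
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from .cardiac_timing import DEFAULT_TD_DIASTOLIC_MS, DEFAULT_TI_DIASTOLIC_MS, DEFAULT_RR_FLOOR_MS

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


class PhantomConfig(BaseModel):
    kind: Literal["cardiac", "vial"] = "cardiac"
    grid: int = Field(650, ge=16)
    pixel_mm: float = Field(1.0, gt=0)
    vial_t1_ms: Optional[list[float]] = None  # vial phantom only; None = default grid

    def to_spec(self):
        from .phantom import PhantomSpec

        return PhantomSpec(grid=self.grid, pixel_mm=self.pixel_mm)


class RRConfig(BaseModel):
    mean_ms: float = Field(667.0, gt=0)
    sd_ms: Optional[float] = Field(None, ge=0)
    arrhythmia_factor: Optional[float] = Field(None, ge=0)
    floor_ms: float = Field(DEFAULT_RR_FLOOR_MS, ge=0)

    @model_validator(mode="after")
    def _one_of(self):
        if self.sd_ms is not None and self.arrhythmia_factor is not None:
            raise ValueError("give either rr.sd_ms or rr.arrhythmia_factor, not both")
        return self

    def resolved_sd(self) -> float:
        if self.sd_ms is not None:
            return self.sd_ms
        if self.arrhythmia_factor is not None:
            return self.arrhythmia_factor * self.mean_ms
        return 0.0


class ScheduleConfig(BaseModel):
    variant: Literal["diastolic", "systolic"] = "diastolic"
    td_ms: float = Field(DEFAULT_TD_DIASTOLIC_MS, gt=0)
    ti_list: list[float] = Field(default_factory=lambda: list(DEFAULT_TI_DIASTOLIC_MS))
    n_frames: int = Field(10, ge=4)
    n_sat: int = 4
    n_inv: int = 5
    ti_spread: tuple[float, float] = (100.0, 300.0)

    @model_validator(mode="after")
    def _consistent(self):
        if self.variant == "diastolic":
            if len(self.ti_list) != self.n_frames:
                object.__setattr__(self, "n_frames", len(self.ti_list))
        else:
            if 1 + self.n_sat + self.n_inv != self.n_frames:
                raise ValueError("schedule.n_frames must equal 1 + n_sat + n_inv")
            if self.ti_spread[1] > self.td_ms:
                raise ValueError("schedule.ti_spread max must not exceed td_ms")
        return self


class MistriggerConfig(BaseModel):
    mode: Literal["none", "threshold", "share"] = "none"


class NoiseConfig(BaseModel):
    snr: Optional[float] = Field(60.0, gt=0)  # None = noiseless


class FitConfig(BaseModel):
    method: Literal["magnitude", "phase_sensitive"] = "phase_sensitive"


class RunConfig(BaseModel):
    """Full description of a simulation run; round-trips through YAML."""

    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    schedule: ScheduleConfig = Field(default_factory=ScheduleConfig)
    rr: RRConfig = Field(default_factory=RRConfig)
    mistrigger: MistriggerConfig = Field(default_factory=MistriggerConfig)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    fit: FitConfig = Field(default_factory=FitConfig)
    conditions_sd_ms: Optional[list[float]] = None
    conditions_factor: Optional[list[float]] = None
    repetitions: int = Field(1, ge=1)
    base_seed: int = 1234
    output_dir: str = "out"

    @model_validator(mode="after")
    def _conditions(self):
        if self.conditions_sd_ms is not None and self.conditions_factor is not None:
            raise ValueError("give either conditions_sd_ms or conditions_factor, not both")
        return self

    def condition_sds_ms(self) -> list[float]:
        if self.conditions_sd_ms is not None:
            return list(self.conditions_sd_ms)
        if self.conditions_factor is not None:
            return [f * self.rr.mean_ms for f in self.conditions_factor]
        return [self.rr.resolved_sd()]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(json.loads(cfg.model_dump_json()), fh, sort_keys=False)


def config_hash(cfg: RunConfig) -> str:
    """Stable hash of the canonical config serialization."""
    canonical = json.dumps(json.loads(cfg.model_dump_json()), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
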