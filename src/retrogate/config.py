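"""Run configuration: a versioned YAML schema mirroring the simulator,
gating, and fitting parameters.

Unknown keys are errors, not warnings, so a typo in a config cannot
silently fall back to a default.  Every pipeline run writes its resolved
configuration next to its outputs so results are reproducible from the
emitted file plus the seed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import phantom as ph

__all__ = [
    "VialConfig",
    "PhantomConfig",
    "ProtocolConfig",
    "HeartbeatConfig",
    "GatingConfig",
    "FitConfig",
    "ModulationConfig",
    "RunConfig",
    "load_config",
    "save_config",
]

CONFIG_VERSION = 1


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class VialConfig(_Strict):
    center: tuple[float, float]
    radius: float = Field(gt=0)
    s0: float = Field(gt=0)
    t2star: float = Field(gt=0)


class PhantomConfig(_Strict):
    grid: tuple[int, int] = (128, 128)
    fov: tuple[float, float] = (30.0, 30.0)
    vials: Optional[list[VialConfig]] = None  # None -> default six-vial layout

    def to_spec(self) -> ph.PhantomSpec:
        if self.vials is None:
            return ph.default_phantom_spec(grid=self.grid)
        return ph.PhantomSpec(
            grid=self.grid,
            fov=self.fov,
            vials=tuple(
                ph.Vial(center=tuple(v.center), radius=v.radius, s0=v.s0, t2star=v.t2star)
                for v in self.vials
            ),
        )


class ProtocolConfig(_Strict):
    tr: float = 14.0
    te1: float = 1.5
    delta_te: float = 1.6
    n_echoes: int = 7
    n_measurements: int = 300
    n_phases: int = 10

    def to_spec(self, matrix: tuple[int, int]) -> ph.ProtocolSpec:
        return ph.ProtocolSpec(
            tr=self.tr,
            te1=self.te1,
            delta_te=self.delta_te,
            n_echoes=self.n_echoes,
            n_measurements=self.n_measurements,
            n_phases=self.n_phases,
            matrix=matrix,
        )


class HeartbeatConfig(_Strict):
    distribution: Literal["constant", "uniform", "gaussian", "replay_from_file"] = "gaussian"
    rr_mean: float = 120.0
    rr_spread: float = 3.0
    failure_rate: float = 0.0
    rr_file: Optional[str] = None

    def to_model(self, seed: int | None) -> ph.HeartbeatModel:
        rr_values = None
        if self.distribution == "replay_from_file":
            if self.rr_file is None:
                raise ValueError("replay_from_file requires rr_file")
            from .io import read_trigger_csv

            import numpy as np

            triggers = read_trigger_csv(self.rr_file)
            rr_values = tuple(np.diff(triggers).tolist())
        return ph.HeartbeatModel(
            distribution=self.distribution,
            rr_mean=self.rr_mean,
            rr_spread=self.rr_spread,
            failure_rate=self.failure_rate,
            seed=seed,
            rr_values=rr_values,
        )


class GatingConfig(_Strict):
    tolerance: float = 0.05
    window: int = 10
    n_phases: int = 10
    systole_phase_offset: int = 0
    min_rr: float = 50.0


class FitConfig(_Strict):
    t2star_bounds: tuple[float, float] = (0.1, 100.0)
    min_gof: Optional[float] = None
    roi_erode_px: float = 2.0


class ModulationConfig(_Strict):
    kind: Literal["constant", "sinusoid"] = "constant"
    factor: float = 1.0
    amplitude: float = 0.2
    phase0: float = 0.0

    def to_modulation(self) -> ph.DynamicModulation:
        if self.kind == "constant":
            return ph.DynamicModulation.constant(self.factor)
        return ph.DynamicModulation.sinusoid(self.amplitude, self.phase0)


class RunConfig(_Strict):
    version: int = CONFIG_VERSION
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    heartbeat: HeartbeatConfig = Field(default_factory=HeartbeatConfig)
    gating: GatingConfig = Field(default_factory=GatingConfig)
    fit: FitConfig = Field(default_factory=FitConfig)
    modulation: ModulationConfig = Field(default_factory=ModulationConfig)
    noise_sd: float = 0.0
    seed: int = 0

    @model_validator(mode="after")
    def _check_version(self) -> "RunConfig":
        if self.version != CONFIG_VERSION:
            raise ValueError(f"unsupported config version {self.version}")
        if self.gating.n_phases != self.protocol.n_phases:
            raise ValueError("gating.n_phases must match protocol.n_phases")
        return self


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(payload)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write the resolved configuration as YAML (lossless round-trip)."""
    payload = config.model_dump(mode="json")
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
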