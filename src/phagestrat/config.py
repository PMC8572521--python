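"""Scenario configuration: YAML schema, defaults, validation, bundled presets.

A scenario file is a YAML mapping with (all optional) sections ``params``,
``initial_state``, ``simulation`` and ``analysis`` plus a ``strategy`` and a
default ``command``; unspecified fields fall back to the study defaults, so
an empty file resolves to the standard parameterization.  Unknown keys are
rejected, ranges are validated (e.g. ``a < 1``), and a loaded config saves
back to an equivalent file (round-trip identity of the resolved values).

Analysis grids are kept within the ranges explored by the study design
(``N0`` in [0.6, 30], amplitude in [0, 0.99], period in [24 h, 1 year])
unless extrapolation is explicitly allowed.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core_model import ModelParams, StrategyKind, SystemState
from .simulate import SimulationSpec

__all__ = [
    "ScenarioConfig",
    "load_config",
    "save_config",
    "load_preset",
    "list_presets",
    "GridSpec",
]

#: grid ranges explored by the study design
N0_RANGE = (0.6, 30.0)
AMPLITUDE_RANGE = (0.0, 0.99)
PERIOD_RANGE = (24.0, 8760.0)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class ParamsSection(_Strict):
    x: float = 0.0206
    y1: float = 7.5
    y2: float = 4.0
    N_H: float = 1.0
    i_norm: float = 5.23
    c: float = 3.14e-4
    n: float = Field(0.02, gt=0, le=1)
    s_max: float = Field(0.33, ge=0)
    d: float = Field(0.0866, ge=0)
    D: float = Field(1.0 / 24.0, ge=0)
    N0: float = Field(2.0, ge=0)
    SH: float = Field(4.0, ge=0)
    r: float = Field(0.5, ge=0)
    H: float = Field(1.0, ge=0)
    s_switch: float = Field(0.0033, ge=0)
    a: float = Field(0.0, ge=0, lt=1)
    T: float = Field(720.0, gt=0)
    shunt_enabled: bool = True

    def to_model_params(self) -> ModelParams:
        return ModelParams(**self.model_dump())


class InitialStateSection(_Strict):
    B1: float = Field(0.83, ge=0)
    B2: float = Field(0.83, ge=0)
    I1: float = Field(0.17, ge=0)
    I2: float = Field(0.17, ge=0)
    P1: float = Field(3.10e-4, ge=0)
    P2: float = Field(3.10e-4, ge=0)
    N: float | None = Field(None, ge=0)  # defaults to N0

    def to_system_state(self, strategy: StrategyKind, N0: float) -> SystemState:
        N = self.N if self.N is not None else N0
        if strategy is StrategyKind.NONE:
            return SystemState(B1=self.B1, B2=self.B2, N=N)
        return SystemState(B1=self.B1, B2=self.B2, I1=self.I1, I2=self.I2,
                           P1=self.P1, P2=self.P2, N=N)


class SimulationSection(_Strict):
    t_end: float = Field(43_800.0, gt=0)
    output_step: float = Field(1.0, gt=0)
    transient_fraction: float = Field(0.8, ge=0, lt=1)
    rel_tol: float = Field(1e-8, gt=0)
    abs_tol: float = Field(1e-8, gt=0)


class GridSpec(_Strict):
    """A numeric grid: explicit values, or start/stop/num (linear or log)."""

    values: list[float] | None = None
    start: float | None = None
    stop: float | None = None
    num: int | None = Field(None, ge=2)
    log: bool = False

    @model_validator(mode="after")
    def _check(self):
        explicit = self.values is not None
        ranged = self.start is not None and self.stop is not None and self.num is not None
        if explicit == ranged:
            raise ValueError("grid needs either 'values' or all of start/stop/num")
        return self

    def resolve(self) -> np.ndarray:
        if self.values is not None:
            return np.asarray(self.values, dtype=float)
        if self.log:
            return np.geomspace(self.start, self.stop, self.num)
        return np.linspace(self.start, self.stop, self.num)


class AnalysisSection(_Strict):
    extinction_threshold: float = Field(1e-6, gt=0)
    N0_grid: GridSpec = GridSpec(start=0.6, stop=30.0, num=60)
    amplitude_grid: GridSpec = GridSpec(start=0.0, stop=0.99, num=25)
    period_grid: GridSpec = GridSpec(start=24.0, stop=8760.0, num=25, log=True)
    sweep_axis: Literal["amplitude", "period"] = "amplitude"
    fluctuating: bool = False          # bifurcation scans: forced variant
    fluct_amplitude: float = Field(0.5, ge=0, lt=1)
    fluct_period: float = Field(168.0, gt=0)
    component: str = "B1"              # threshold command
    bracket: tuple[float, float] = (5.0, 30.0)
    tolerance: float = Field(0.1, gt=0)


class ScenarioConfig(_Strict):
    """Fully resolved scenario: strategy + parameters + solver + analysis."""

    name: str = "scenario"
    strategy: StrategyKind = StrategyKind.LYTIC
    command: Literal["timeseries", "bifurcation", "sweep", "threshold"] = "timeseries"
    params: ParamsSection = ParamsSection()
    initial_state: InitialStateSection = InitialStateSection()
    simulation: SimulationSection = SimulationSection()
    analysis: AnalysisSection = AnalysisSection()

    @model_validator(mode="after")
    def _cross_checks(self):
        # delegate the coupled-parameter invariants to the model layer
        self.params.to_model_params()
        return self

    def model_params(self) -> ModelParams:
        return self.params.to_model_params()

    def simulation_spec(self) -> SimulationSpec:
        params = self.model_params()
        return SimulationSpec(
            strategy=self.strategy,
            params=params,
            initial_state=self.initial_state.to_system_state(self.strategy, params.N0),
            **self.simulation.model_dump(),
        )

    def validate_grid_ranges(self, allow_extrapolation: bool = False) -> None:
        """Reject grids outside the ranges the study design explored."""
        if allow_extrapolation:
            return
        checks = [
            ("N0_grid", self.analysis.N0_grid.resolve(), N0_RANGE),
            ("amplitude_grid", self.analysis.amplitude_grid.resolve(), AMPLITUDE_RANGE),
            ("period_grid", self.analysis.period_grid.resolve(), PERIOD_RANGE),
        ]
        for name, grid, (lo, hi) in checks:
            if grid.min() < lo - 1e-12 or grid.max() > hi + 1e-12:
                raise ValueError(
                    f"{name} [{grid.min():g}, {grid.max():g}] outside the studied "
                    f"range [{lo:g}, {hi:g}]; pass --allow-extrapolation to override"
                )


def load_config(path) -> ScenarioConfig:
    """Load a YAML scenario file, merging defaults for unspecified fields."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"scenario file {path} must contain a YAML mapping")
    return ScenarioConfig.model_validate(data)


def save_config(config: ScenarioConfig, path) -> None:
    """Write the fully resolved scenario back to YAML (round-trips exactly)."""
    data = config.model_dump(mode="json")
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def list_presets() -> list[str]:
    """Names of the bundled scenario presets."""
    pkg = resources.files("phagestrat") / "presets"
    return sorted(p.name.removesuffix(".yaml") for p in pkg.iterdir()
                  if p.name.endswith(".yaml"))


def load_preset(name: str) -> ScenarioConfig:
    """Load a bundled preset by name (see :func:`list_presets`)."""
    pkg = resources.files("phagestrat") / "presets" / f"{name}.yaml"
    if not pkg.is_file():
        raise FileNotFoundError(
            f"no preset {name!r}; available: {', '.join(list_presets())}"
        )
    data = yaml.safe_load(pkg.read_text())
    return ScenarioConfig.model_validate(data)
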