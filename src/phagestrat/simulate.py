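"""Numerical integration of the chemostat model into sampled trajectories.

A :class:`SimulationSpec` bundles strategy, parameters, initial condition and
solver settings; :func:`run_simulation` integrates it with the adaptive
Cash-Karp 5(4) stepper and returns a :class:`Trajectory` sampled on a regular
grid.  :func:`final_window` restricts a trajectory to the post-transient
window used by all attractor-level analyses.  Trajectories round-trip through
plain CSV (``time_h,B1,B2,I1,I2,P1,P2,N``), optionally with a denormalized
companion in particles mL^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _rk
from .core_model import (
    STATE_FIELDS,
    STRATEGY_CODES,
    ModelParams,
    StrategyKind,
    SystemState,
    default_initial_state,
)
from .units import RawQuantities, denormalize_abundance

__all__ = [
    "SimulationSpec",
    "Trajectory",
    "IntegrationError",
    "run_simulation",
    "final_window",
    "write_trajectory_csv",
    "read_trajectory_csv",
]

#: which compartments denormalize with the phage conversion
_PHAGE_COLUMNS = frozenset({"P1", "P2"})


class IntegrationError(RuntimeError):
    """Raised when the adaptive stepper fails (underflow / non-finite state)."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(message)
        self.t_fail = t_fail


@dataclass(frozen=True)
class SimulationSpec:
    """Everything needed to reproduce one trajectory.

    ``transient_fraction`` is the leading fraction of ``t_end`` discarded by
    :func:`final_window` before any attractor-level analysis.
    """

    strategy: StrategyKind
    params: ModelParams = field(default_factory=ModelParams)
    initial_state: SystemState | None = None
    t_end: float = 43_800.0          # 5 years of hours
    output_step: float = 1.0
    transient_fraction: float = 0.8
    rel_tol: float = 1e-8
    abs_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.output_step <= 0:
            raise ValueError("output_step must be positive")
        if not 0.0 <= self.transient_fraction < 1.0:
            raise ValueError("transient_fraction must be in [0, 1)")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be positive")

    def resolve_initial_state(self) -> SystemState:
        if self.initial_state is not None:
            return self.initial_state
        return default_initial_state(self.strategy, self.params)


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped state sequence produced by one simulation."""

    times: np.ndarray              # shape (n,), hours, strictly increasing
    states: np.ndarray             # shape (n, 7), columns in STATE_FIELDS order
    spec: SimulationSpec | None = None

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have equal length")
        if self.states.ndim != 2 or self.states.shape[1] != 7:
            raise ValueError("states must have shape (n, 7)")

    def __len__(self) -> int:
        return len(self.times)

    def series(self, name: str) -> np.ndarray:
        """Column of one state variable (``'B1'`` ... ``'N'``)."""
        return self.states[:, STATE_FIELDS.index(name)]

    @property
    def final_state(self) -> SystemState:
        return SystemState.from_array(self.states[-1])

    def to_dataframe(self, raw: RawQuantities | None = None) -> pd.DataFrame:
        """As a DataFrame; pass ``raw`` to get abundances in particles mL^-1."""
        if raw is None:
            data = {"time_h": self.times}
            for j, name in enumerate(STATE_FIELDS):
                data[name] = self.states[:, j]
            return pd.DataFrame(data)
        data = {"time_h": self.times}
        for j, name in enumerate(STATE_FIELDS):
            kind = "phage" if name in _PHAGE_COLUMNS else "bacteria"
            data[f"{name}_particles_per_ml"] = np.array(
                [denormalize_abundance(max(v, 0.0), kind, raw) for v in self.states[:, j]]
            )
        return pd.DataFrame(data)


def run_simulation(spec: SimulationSpec) -> Trajectory:
    """Integrate the model from t=0 to ``spec.t_end``.

    With the ``NONE`` strategy the infected and phage compartments are
    required to start at zero and then remain identically zero.
    """
    y0 = spec.resolve_initial_state().to_array()
    if np.any(y0 < 0):
        raise ValueError("initial state components must be non-negative")
    if spec.strategy is StrategyKind.NONE and np.any(y0[2:6] != 0.0):
        raise ValueError("NONE strategy requires zero infected/phage initial densities")

    ts, ys, status, t_fail = _rk.integrate(
        STRATEGY_CODES[spec.strategy],
        spec.params.to_array(),
        spec.params.shunt_enabled,
        y0,
        spec.t_end,
        spec.output_step,
        spec.rel_tol,
        spec.abs_tol,
    )
    if status != 0:
        raise IntegrationError(
            f"integration failed at t={t_fail:.3f} h (step underflow or non-finite state)",
            t_fail,
        )
    return Trajectory(times=ts, states=ys, spec=spec)


def final_window(traj: Trajectory) -> Trajectory:
    """Restrict to the post-transient window ``t >= transient_fraction * t_end``."""
    if traj.spec is None:
        raise ValueError("trajectory has no spec; cannot locate the transient")
    t0 = traj.spec.transient_fraction * traj.spec.t_end
    mask = traj.times >= t0 - 1e-9
    if not mask.any():
        raise ValueError("post-transient window is empty")
    return Trajectory(times=traj.times[mask], states=traj.states[mask], spec=traj.spec)


def write_trajectory_csv(traj: Trajectory, path, raw: RawQuantities | None = None) -> None:
    """Write ``time_h,B1,...,N`` CSV; with ``raw``, columns are particles mL^-1."""
    traj.to_dataframe(raw).to_csv(path, index=False, float_format="%.10g")


def read_trajectory_csv(path, spec: SimulationSpec | None = None) -> Trajectory:
    """Read a normalized-units trajectory CSV written by :func:`write_trajectory_csv`."""
    df = pd.read_csv(path)
    expected = ["time_h", *STATE_FIELDS]
    if list(df.columns) != expected:
        raise ValueError(f"unexpected columns {list(df.columns)}; expected {expected}")
    return Trajectory(
        times=df["time_h"].to_numpy(float),
        states=df[list(STATE_FIELDS)].to_numpy(float),
        spec=spec,
    )
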