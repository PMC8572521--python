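"""Attractor-level analysis: persistence codes, extrema, bifurcation scans, 2-D sweeps.

All analyses operate on the post-transient window of a trajectory (see
:func:`phagestrat.simulate.final_window`).  A community member *survives* a
run when its maximum density over that window stays at or above an extinction
threshold (default 1e-6 normalized, roughly 10 bacteria mL^-1) — the maximum,
not the final value, so oscillating populations that dip low are not
misclassified.  Phage and its infected host compartment count as one
"infection" state, giving the 0-4 persistence code:

====  =============================================================
code  surviving states
====  =============================================================
0     none
1     fast-growing bacteria
2     fast-growing bacteria + their infection
3     both bacteria + the fast grower's infection
4     both bacteria + both infections
====  =============================================================

Off-ladder survival combinations (e.g. the PtW regime where the uninfected
fast grower dies while its lysogenic infected compartment persists) keep
their full flag vector; the code is the count of surviving states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core_model import STATE_FIELDS, ModelParams, StrategyKind
from .simulate import (
    IntegrationError,
    SimulationSpec,
    Trajectory,
    final_window,
    run_simulation,
)

__all__ = [
    "PersistenceState",
    "ExtremaResult",
    "BifurcationDiagram",
    "SweepResult",
    "classify_persistence",
    "detect_extrema",
    "bifurcation_scan",
    "sweep_2d",
    "find_critical_N0",
    "bisect_boolean",
    "DEFAULT_EXTINCTION_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: ~10 bacteria mL^-1: far below every attractor scale, far above solver noise
DEFAULT_EXTINCTION_THRESHOLD = 1e-6

#: names of the four community states, in ladder order
STATE_LADDER = ("B1", "infection1", "B2", "infection2")

#: relative amplitude below which a series counts as steady
_STEADY_REL_AMPLITUDE = 1e-3


@dataclass(frozen=True)
class PersistenceState:
    """Survival flags for the four community states and their count code."""

    code: int
    survived: dict[str, bool]

    @classmethod
    def from_flags(cls, b1: bool, inf1: bool, b2: bool, inf2: bool) -> "PersistenceState":
        flags = {"B1": b1, "infection1": inf1, "B2": b2, "infection2": inf2}
        return cls(code=sum(flags.values()), survived=flags)


@dataclass(frozen=True)
class ExtremaResult:
    """Post-transient extrema of one scalar series.

    A series whose relative amplitude ``(max - min)/max`` stays at or below
    1e-3 is steady and carries its mean as the single extremum; otherwise the
    interior local minima/maxima are reported.
    """

    steady: bool
    minima: np.ndarray
    maxima: np.ndarray

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.minima, self.maxima])


def component_survival(traj: Trajectory,
                       extinction_threshold: float = DEFAULT_EXTINCTION_THRESHOLD,
                       ) -> dict[str, bool]:
    """Per-variable survival over the post-transient window (max >= threshold)."""
    win = final_window(traj)
    surv = {name: bool(win.series(name).max() >= extinction_threshold)
            for name in STATE_FIELDS if name != "N"}
    surv["infection1"] = surv["I1"] and surv["P1"]
    surv["infection2"] = surv["I2"] and surv["P2"]
    return surv


def classify_persistence(traj: Trajectory,
                         extinction_threshold: float = DEFAULT_EXTINCTION_THRESHOLD,
                         ) -> PersistenceState:
    """Map a trajectory to its 0-4 persistence code plus survival flags."""
    surv = component_survival(traj, extinction_threshold)
    return PersistenceState.from_flags(
        surv["B1"], surv["infection1"], surv["B2"], surv["infection2"]
    )


def detect_extrema(series: Sequence[float]) -> ExtremaResult:
    """Local extrema of a post-transient scalar series.

    Uses sign changes of the discrete differences (plateaus are carried
    forward).  A monotone, still-converging series has no interior extrema
    and falls back to its overall min/max.
    """
    values = np.asarray(series, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 samples to detect extrema")
    vmax = values.max()
    vmin = values.min()
    scale = abs(vmax)
    if scale == 0.0 or (vmax - vmin) / scale <= _STEADY_REL_AMPLITUDE:
        return ExtremaResult(steady=True,
                             minima=np.array([values.mean()]),
                             maxima=np.array([values.mean()]))
    d = np.sign(np.diff(values))
    # carry the previous slope through plateaus
    for i in range(1, d.size):
        if d[i] == 0:
            d[i] = d[i - 1]
    turns = np.nonzero(d[1:] * d[:-1] < 0)[0] + 1
    maxima = values[turns[d[turns] < 0]] if turns.size else np.array([])
    minima = values[turns[d[turns] > 0]] if turns.size else np.array([])
    if maxima.size == 0 and minima.size == 0:
        return ExtremaResult(steady=False,
                             minima=np.array([vmin]), maxima=np.array([vmax]))
    return ExtremaResult(steady=False, minima=np.asarray(minima),
                         maxima=np.asarray(maxima))


@dataclass(frozen=True)
class BifurcationDiagram:
    """Per-``N0`` post-transient extrema and persistence classification."""

    strategy: StrategyKind
    N0_values: np.ndarray
    extrema: list[dict[str, ExtremaResult] | None]   # None where integration failed
    persistence: list[PersistenceState | None]
    failures: dict[int, str] = field(default_factory=dict)

    def min_N0_with_code(self, min_code: int) -> float:
        """Smallest scanned N0 whose persistence code reaches ``min_code``."""
        for N0, state in zip(self.N0_values, self.persistence):
            if state is not None and state.code >= min_code:
                return float(N0)
        return float("nan")

    def to_frame(self) -> pd.DataFrame:
        """Long format: ``N0,variable,extremum_type,value``."""
        rows = []
        for N0, ext in zip(self.N0_values, self.extrema):
            if ext is None:
                continue
            for name, res in ext.items():
                if res.steady:
                    rows.append((N0, name, "steady", res.minima[0]))
                else:
                    rows.extend((N0, name, "min", v) for v in res.minima)
                    rows.extend((N0, name, "max", v) for v in res.maxima)
        return pd.DataFrame(rows, columns=["N0", "variable", "extremum_type", "value"])


def _run_cell(strategy: StrategyKind, params: ModelParams,
              sim_kwargs: dict) -> Trajectory:
    spec = SimulationSpec(strategy=strategy, params=params, **sim_kwargs)
    return run_simulation(spec)


def bifurcation_scan(strategy: StrategyKind,
                     params: ModelParams,
                     N0_grid: Sequence[float],
                     fluctuating: bool = False,
                     amplitude: float = 0.5,
                     period: float = 168.0,
                     extinction_threshold: float = DEFAULT_EXTINCTION_THRESHOLD,
                     **sim_kwargs) -> BifurcationDiagram:
    """One simulation per supply concentration; extrema + persistence per point.

    The fluctuating variant defaults to a relative amplitude of 0.5 with a
    7-day period.  Integration failures are recorded per grid point rather
    than aborting the scan.
    """
    N0_grid = np.asarray(N0_grid, dtype=float)
    extrema: list[dict[str, ExtremaResult] | None] = []
    persistence: list[PersistenceState | None] = []
    failures: dict[int, str] = {}
    for idx, N0 in enumerate(N0_grid):
        p = params.replace(N0=float(N0),
                           a=amplitude if fluctuating else 0.0,
                           T=period if fluctuating else params.T)
        try:
            traj = _run_cell(strategy, p, sim_kwargs)
        except IntegrationError as exc:
            logger.warning("bifurcation point N0=%g failed: %s", N0, exc)
            failures[idx] = str(exc)
            extrema.append(None)
            persistence.append(None)
            continue
        win = final_window(traj)
        surv = component_survival(traj, extinction_threshold)
        point = {}
        for name in STATE_FIELDS:
            if name != "N" and not surv[name]:
                point[name] = ExtremaResult(steady=True,
                                            minima=np.array([0.0]),
                                            maxima=np.array([0.0]))
            else:
                point[name] = detect_extrema(win.series(name))
        extrema.append(point)
        persistence.append(PersistenceState.from_flags(
            surv["B1"], surv["infection1"], surv["B2"], surv["infection2"]))
    return BifurcationDiagram(strategy=strategy, N0_values=N0_grid,
                              extrema=extrema, persistence=persistence,
                              failures=failures)


@dataclass(frozen=True)
class SweepResult:
    """Persistence codes on a (fluctuation axis) x (supply N0) grid."""

    strategy: StrategyKind
    axis_name: str                  # "amplitude" or "period"
    axis_values: np.ndarray
    N0_values: np.ndarray
    codes: np.ndarray               # int matrix, -1 where integration failed
    flags: np.ndarray               # bool matrix (axis, N0, 4) in STATE_LADDER order
    failures: dict[tuple[int, int], str] = field(default_factory=dict)

    def code4_count(self) -> int:
        return int((self.codes == 4).sum())

    def to_tsv(self, path) -> None:
        """Matrix form: rows = fluctuation axis, columns = N0, cells = code."""
        df = pd.DataFrame(self.codes,
                          index=pd.Index(self.axis_values, name=self.axis_name),
                          columns=pd.Index(self.N0_values, name="N0"))
        df.to_csv(path, sep="\t")

    def to_frame(self) -> pd.DataFrame:
        """Long format with the four survival flags per cell."""
        rows = []
        for i, av in enumerate(self.axis_values):
            for j, N0 in enumerate(self.N0_values):
                rows.append((av, N0, self.codes[i, j], *self.flags[i, j]))
        return pd.DataFrame(
            rows, columns=[self.axis_name, "N0", "code", *STATE_LADDER]
        )


def sweep_2d(strategy: StrategyKind,
             params: ModelParams,
             axis: str,
             axis_grid: Sequence[float],
             N0_grid: Sequence[float],
             fixed_period: float = 720.0,
             fixed_amplitude: float = 0.9,
             extinction_threshold: float = DEFAULT_EXTINCTION_THRESHOLD,
             **sim_kwargs) -> SweepResult:
    """Persistence classification over a fluctuation-by-supply grid.

    ``axis='amplitude'`` varies the relative amplitude ``a`` at a fixed
    30-day period; ``axis='period'`` varies the period ``T`` (typically
    log-spaced from 1 day to 1 year) at a fixed amplitude of 0.9.
    """
    if axis not in ("amplitude", "period"):
        raise ValueError(f"axis must be 'amplitude' or 'period', got {axis!r}")
    axis_grid = np.asarray(axis_grid, dtype=float)
    N0_grid = np.asarray(N0_grid, dtype=float)
    codes = np.full((axis_grid.size, N0_grid.size), -1, dtype=int)
    flags = np.zeros((axis_grid.size, N0_grid.size, 4), dtype=bool)
    failures: dict[tuple[int, int], str] = {}
    for i, av in enumerate(axis_grid):
        for j, N0 in enumerate(N0_grid):
            if axis == "amplitude":
                p = params.replace(N0=float(N0), a=float(av), T=fixed_period)
            else:
                p = params.replace(N0=float(N0), a=fixed_amplitude, T=float(av))
            try:
                traj = _run_cell(strategy, p, sim_kwargs)
            except IntegrationError as exc:
                logger.warning("sweep cell (%s=%g, N0=%g) failed: %s",
                               axis, av, N0, exc)
                failures[(i, j)] = str(exc)
                continue
            state = classify_persistence(traj, extinction_threshold)
            codes[i, j] = state.code
            flags[i, j] = [state.survived[name] for name in STATE_LADDER]
    return SweepResult(strategy=strategy, axis_name=axis, axis_values=axis_grid,
                       N0_values=N0_grid, codes=codes, flags=flags,
                       failures=failures)


def bisect_boolean(predicate: Callable[[float], bool],
                   lo: float, hi: float, tol: float) -> float:
    """Bisection on a boolean predicate that flips once between lo and hi.

    Returns the midpoint of the final bracket, within ``tol`` of the
    transition.  Raises if the predicate does not differ at the endpoints.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    p_lo = predicate(lo)
    p_hi = predicate(hi)
    if p_lo == p_hi:
        raise ValueError(
            f"bracket [{lo}, {hi}] does not straddle a transition "
            f"(predicate is {p_lo} at both ends)"
        )
    while (hi - lo) / 2.0 > tol:
        mid = 0.5 * (lo + hi)
        if predicate(mid) == p_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def find_critical_N0(strategy: StrategyKind,
                     params: ModelParams,
                     component: str,
                     bracket: tuple[float, float],
                     tolerance: float = 0.1,
                     extinction_threshold: float = DEFAULT_EXTINCTION_THRESHOLD,
                     **sim_kwargs) -> float:
    """Supply concentration at which a community member appears/disappears.

    ``component`` is a state variable (``'B1'`` ... ``'P2'``) or an infection
    state (``'infection1'``/``'infection2'``).  Survival at each trial N0 is
    decided by a full simulation; the bracket must straddle the transition.
    """
    valid = set(STATE_FIELDS) - {"N"} | {"infection1", "infection2"}
    if component not in valid:
        raise ValueError(f"unknown component {component!r}; expected one of {sorted(valid)}")

    def survives(N0: float) -> bool:
        p = params.replace(N0=float(N0))
        traj = _run_cell(strategy, p, sim_kwargs)
        return component_survival(traj, extinction_threshold)[component]

    lo, hi = bracket
    if not lo < hi:
        raise ValueError("bracket must satisfy lo < hi")
    return bisect_boolean(survives, lo, hi, tolerance)
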