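"""Chemostat model of two competing bacteria, their phages, and a shared nutrient pool.

The community consists of a fast- and a slow-growing bacterial species
(``B1``, ``B2``), their phage-infected counterparts (``I1``, ``I2``), the free
phage populations (``P1``, ``P2``), and a single dissolved nutrient pool
(``N``).  All densities are normalized biovolumes: laboratory abundances
(particles mL^-1) are converted to biovolume and divided by the bacterial
half-saturation biovolume, so the half-saturation density is 1 by construction
(see :mod:`phagestrat.units`).

Uninfected bacteria grow with a Type-2 (Monod) functional response
``G_k(N) = x * y_k * N / (N + N_H)``, pay a metabolic loss ``x`` and are
infected by their phage at a mass-action rate ``i * B_k * P_k``.  Infected
bacteria are lysed at a rate ``s_k`` that encodes the phage strategy:

* ``LYTIC``  — constant lysis, ``s_k = s_max``.
* ``PTL``    — "Piggyback-the-Loser": lysis rises sigmoidally with total host
  density, ``s_max * (B+I)^2 / ((B+I)^2 + SH)``; lysogeny when hosts are rare.
* ``PTW``    — "Piggyback-the-Winner": lysis is suppressed at high host
  density, ``s_max / (((B+I) * r)^2 + H)``; lysogeny when hosts abound.
* ``NONE``   — no phage at all (pure resource competition).

Whether an infected cell behaves lysogenically (grows and consumes nutrient
with its prophage) or lytically (no reproduction) is decided by a single
switching point on the lysis rate: growth is on whenever the current
strategy-dependent lysis rate is at or below ``s_switch``.  Lysis releases a
fraction ``n`` of the host biovolume as phage particles and, when the viral
shunt is enabled, returns the remaining ``1 - n`` to the nutrient pool.

The chemostat supplies nutrient at concentration ``N0`` with turnover rate
``D``; environmental variability is modelled by a sinusoidal modulation of the
turnover rate with relative amplitude ``a`` and period ``T``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from enum import Enum

import numpy as np

__all__ = [
    "StrategyKind",
    "ModelParams",
    "SystemState",
    "STATE_FIELDS",
    "growth_rate",
    "lysis_rate",
    "growth_enabled",
    "switch_density",
    "turnover_rate",
    "derivatives",
]


class StrategyKind(str, Enum):
    """Which lysis law is active."""

    NONE = "NONE"    #: no phage; infected and phage compartments held at zero
    LYTIC = "LYTIC"  #: constant lysis rate s_max
    PTW = "PTW"      #: Piggyback-the-Winner: lysogeny at high host density
    PTL = "PTL"      #: Piggyback-the-Loser: lysogeny at low host density


#: integer codes shared with the compiled integrator kernel
STRATEGY_CODES = {
    StrategyKind.NONE: 0,
    StrategyKind.LYTIC: 1,
    StrategyKind.PTW: 2,
    StrategyKind.PTL: 3,
}

#: state-vector component names, in canonical order
STATE_FIELDS = ("B1", "B2", "I1", "I2", "P1", "P2", "N")

#: parameter-vector layout shared with the compiled integrator kernel
PARAM_FIELDS = (
    "x", "y1", "y2", "N_H", "i_norm", "c", "n", "s_max", "d", "D",
    "N0", "SH", "r", "H", "s_switch", "a", "T",
)


@dataclass(frozen=True)
class ModelParams:
    """All rates and conversion constants, in normalized units.

    Defaults are the standard parameterization shared by all bundled
    scenarios; only ``N0`` (supply concentration), the forcing parameters
    ``a``/``T`` and the growth constants ``y1``/``y2`` are varied between
    scenarios.

    Parameters
    ----------
    x : float
        Metabolic rate of heterotrophic bacteria [h^-1]; also the per-capita
        metabolic loss of both species.
    y1, y2 : float
        Dimensionless metabolic scaling constants; species 1 grows fast
        (``y1 > y2``).  Maximum growth rate of species k is ``x * y_k``.
    N_H : float
        Half-saturation density, 1.0 by construction in normalized units.
    i_norm : float
        Normalized phage adsorption rate [h^-1] (see
        :func:`phagestrat.units.normalize_adsorption`).
    c : float
        Phage-to-bacterium biovolume ratio; scales the biovolume transferred
        from the phage pool during adsorption.
    n : float
        Burst volume fraction: share of lysed host biovolume that becomes
        phage particles.  The remaining ``1 - n`` is the viral shunt.
    s_max : float
        Maximum lysis rate [h^-1]; the constant lytic rate.
    d : float
        Free-phage decay rate [h^-1].
    D : float
        Mean chemostat turnover rate [h^-1].
    N0 : float
        Nutrient supply concentration, normalized.
    SH : float
        Half-saturation (squared-density) constant of the PtL lysis law.
    r, H : float
        Correction parameters of the PtW lysis law.
    s_switch : float
        Lysis rate at the lysogenic/lytic switching point [h^-1]; infected
        cells grow iff their current lysis rate is <= this value.
    a : float
        Relative amplitude of the turnover-rate fluctuation, in [0, 1).
    T : float
        Fluctuation period [h]; required positive when ``a > 0``.
    shunt_enabled : bool
        Whether lysate nutrients (fraction ``1 - n``) return to the pool.
    """

    x: float = 0.0206
    y1: float = 7.5
    y2: float = 4.0
    N_H: float = 1.0
    i_norm: float = 5.23
    c: float = 3.14e-4
    n: float = 0.02
    s_max: float = 0.33
    d: float = 0.0866
    D: float = 1.0 / 24.0
    N0: float = 2.0
    SH: float = 4.0
    r: float = 0.5
    H: float = 1.0
    s_switch: float = 0.0033
    a: float = 0.0
    T: float = 720.0
    shunt_enabled: bool = True

    def __post_init__(self) -> None:
        for name in ("x", "N_H", "i_norm", "c", "n", "s_max", "d", "D",
                     "N0", "SH", "r", "H", "s_switch"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if not 0.0 <= self.a < 1.0:
            raise ValueError(f"fluctuation amplitude a must satisfy 0 <= a < 1, got {self.a}")
        if not 0.0 < self.n <= 1.0:
            raise ValueError(f"burst volume fraction n must be in (0, 1], got {self.n}")
        if not self.y1 > self.y2 > 1.0:
            raise ValueError(
                f"growth constants must satisfy y1 > y2 > 1, got y1={self.y1}, y2={self.y2}"
            )
        if not self.s_switch < self.s_max:
            raise ValueError(
                f"switch point s_switch={self.s_switch} must lie below s_max={self.s_max}"
            )
        if self.a > 0 and not self.T > 0:
            raise ValueError("fluctuation period T must be positive when a > 0")

    def to_array(self) -> np.ndarray:
        """Pack into the float vector layout used by the integrator kernel."""
        return np.array([getattr(self, name) for name in PARAM_FIELDS], dtype=np.float64)

    def replace(self, **changes) -> "ModelParams":
        from dataclasses import replace as _replace

        return _replace(self, **changes)


@dataclass(frozen=True)
class SystemState:
    """The 7 state variables, as normalized biovolume densities."""

    B1: float
    B2: float
    I1: float = 0.0
    I2: float = 0.0
    P1: float = 0.0
    P2: float = 0.0
    N: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in STATE_FIELDS], dtype=np.float64)

    @classmethod
    def from_array(cls, arr) -> "SystemState":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (7,):
            raise ValueError(f"state vector must have shape (7,), got {arr.shape}")
        return cls(*arr)


def default_initial_state(strategy: StrategyKind, params: ModelParams) -> SystemState:
    """The common initial condition used for all scenarios.

    Bacteria start at 0.83, infected bacteria at 0.17 (an 83:17 split of the
    initial population), phages at the printed normalized density 3.10e-4, and
    the nutrient pool at the supply concentration ``N0``.  With the ``NONE``
    strategy the infection compartments start (and stay) at zero.
    """
    if strategy is StrategyKind.NONE:
        return SystemState(B1=0.83, B2=0.83, N=params.N0)
    return SystemState(B1=0.83, B2=0.83, I1=0.17, I2=0.17,
                       P1=3.10e-4, P2=3.10e-4, N=params.N0)


def growth_rate(N: float, y_k: float, params: ModelParams) -> float:
    """Per-capita Type-2 growth rate ``x * y_k * N / (N + N_H)`` [h^-1].

    Strictly increasing in ``N`` and saturating at ``x * y_k``.
    """
    if N < 0:
        raise ValueError(f"nutrient density must be non-negative, got {N}")
    return params.x * y_k * N / (N + params.N_H)


def lysis_rate(strategy: StrategyKind, B_k: float, I_k: float,
               params: ModelParams) -> float:
    """Strategy-dependent lysis rate of infected bacteria [h^-1].

    ``LYTIC`` is constant at ``s_max``; ``PTL`` increases sigmoidally with the
    total host density ``B_k + I_k``; ``PTW`` decreases with it; ``NONE`` has
    no phage and returns 0.
    """
    if B_k < 0 or I_k < 0:
        raise ValueError("host densities must be non-negative")
    if strategy is StrategyKind.NONE:
        return 0.0
    if strategy is StrategyKind.LYTIC:
        return params.s_max
    total = B_k + I_k
    if strategy is StrategyKind.PTL:
        return params.s_max * total * total / (total * total + params.SH)
    if strategy is StrategyKind.PTW:
        scaled = total * params.r
        return params.s_max / (scaled * scaled + params.H)
    raise ValueError(f"unknown strategy {strategy!r}")


def growth_enabled(strategy: StrategyKind, current_lysis_rate: float,
                   params: ModelParams) -> bool:
    """Whether infected bacteria currently grow (lysogenic behaviour).

    For the temperate strategies the prophage lets its host reproduce whenever
    the lysis rate is at or below the switching point ``s_switch``; a purely
    lytic infection never allows host reproduction.  Because the PtL lysis
    rate is low at LOW host density and the PtW rate is low at HIGH host
    density, this single rule yields lysogeny-when-rare for PtL and
    lysogeny-when-abundant for PtW.
    """
    if current_lysis_rate < 0:
        raise ValueError("lysis rate must be non-negative")
    if strategy in (StrategyKind.PTW, StrategyKind.PTL):
        return current_lysis_rate <= params.s_switch
    return False


def switch_density(strategy: StrategyKind, params: ModelParams) -> float:
    """Total host density at which the lysis rate equals ``s_switch``.

    Inverts the PtL or PtW lysis law at the switching point.  For PtL,
    ``s_max * q^2 / (q^2 + SH) = s_switch`` gives
    ``q = sqrt(s_switch * SH / (s_max - s_switch))``; for PtW,
    ``s_max / ((q r)^2 + H) = s_switch`` gives
    ``q = sqrt(s_max / s_switch - H) / r``.
    """
    p = params
    if strategy is StrategyKind.PTL:
        return math.sqrt(p.s_switch * p.SH / (p.s_max - p.s_switch))
    if strategy is StrategyKind.PTW:
        arg = p.s_max / p.s_switch - p.H
        if arg <= 0:
            raise ValueError("PtW lysis rate never drops to s_switch with these parameters")
        return math.sqrt(arg) / p.r
    raise ValueError(f"switch density is defined only for PTW/PTL, not {strategy!r}")


def turnover_rate(t: float, params: ModelParams) -> float:
    """Sinusoidally modulated chemostat turnover rate [h^-1].

    ``D_F(t) = a * D * sin(2 pi t / T) + D``; the mean over one period is
    ``D`` and positivity is guaranteed by ``a < 1``.
    """
    if params.a == 0.0:
        return params.D
    return params.a * params.D * math.sin(2.0 * math.pi * t / params.T) + params.D


def derivatives(t: float, state: SystemState, strategy: StrategyKind,
                params: ModelParams) -> SystemState:
    """Right-hand side of the ODE system; returns d(state)/dt.

    Components marginally below zero (integrator round-off) are clamped to
    zero before rates are evaluated; no floor is imposed on the solution
    itself.  The nutrient pool is shared, so consumption and the viral shunt
    sum over both species; an infected compartment consumes nutrient exactly
    when its growth switch is on.
    """
    p = params
    y = state.to_array()
    if not np.all(np.isfinite(y)):
        raise FloatingPointError(f"non-finite state at t={t}: {y}")
    y = np.maximum(y, 0.0)
    B = (y[0], y[1])
    I = (y[2], y[3])
    P = (y[4], y[5])
    N = y[6]

    dB = [0.0, 0.0]
    dI = [0.0, 0.0]
    dP = [0.0, 0.0]
    dN = turnover_rate(t, p) * (p.N0 - N)

    for k in range(2):
        y_k = p.y1 if k == 0 else p.y2
        G = growth_rate(N, y_k, p)
        if strategy is StrategyKind.NONE:
            dB[k] = G * B[k] - p.x * B[k]
            dN -= G * B[k]
            continue
        s_k = lysis_rate(strategy, B[k], I[k], p)
        g_k = growth_enabled(strategy, s_k, p)
        infection = p.i_norm * B[k] * P[k]
        dB[k] = G * B[k] - p.x * B[k] - infection
        dI[k] = (1.0 + p.c) * infection - p.x * I[k] - s_k * I[k]
        if g_k:
            dI[k] += G * I[k]
        dP[k] = p.n * s_k * I[k] - p.c * infection - p.d * P[k]
        dN -= G * B[k]
        if g_k:
            dN -= G * I[k]
        if p.shunt_enabled:
            dN += (1.0 - p.n) * s_k * I[k]

    return SystemState(dB[0], dB[1], dI[0], dI[1], dP[0], dP[1], dN)
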