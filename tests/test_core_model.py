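"""Unit and property tests for the model's rate laws and ODE right-hand side."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagestrat import (
    ModelParams,
    StrategyKind,
    SystemState,
    derivatives,
    growth_enabled,
    growth_rate,
    lysis_rate,
    switch_density,
    turnover_rate,
)
from phagestrat.core_model import default_initial_state

P = ModelParams()


class TestGrowthRate:
    def test_no_nutrient_no_growth(self):
        assert growth_rate(0.0, 7.5, P) == 0.0

    def test_saturates_at_x_times_y(self):
        assert growth_rate(1e12, 7.5, P) == pytest.approx(P.x * 7.5, rel=1e-9)

    def test_half_saturation_value(self):
        # x*y*N/(N+N_H) at N = N_H = 1: half the maximum
        assert growth_rate(1.0, 7.5, P) == pytest.approx(0.077250, abs=1e-9)

    def test_monotone_in_nutrient(self):
        N = np.linspace(0.0, 30.0, 200)
        g = np.array([growth_rate(v, 4.0, P) for v in N])
        assert (np.diff(g) > 0).all()

    def test_negative_nutrient_rejected(self):
        with pytest.raises(ValueError):
            growth_rate(-0.1, 7.5, P)


class TestLysisRate:
    def test_lytic_constant(self):
        for density in (0.0, 0.5, 19.9, 400.0):
            assert lysis_rate(StrategyKind.LYTIC, density, 0.0, P) == 0.33

    def test_none_is_zero(self):
        assert lysis_rate(StrategyKind.NONE, 5.0, 1.0, P) == 0.0

    def test_ptl_switch_point_density(self):
        # host density at which the PtL lysis rate hits the switching value
        assert lysis_rate(StrategyKind.PTL, 0.2010076, 0.0, P) == pytest.approx(
            0.0033, rel=1e-6)

    def test_ptw_switch_point_density(self):
        assert lysis_rate(StrategyKind.PTW, 19.8997500, 0.0, P) == pytest.approx(
            0.0033, rel=1e-6)

    def test_zero_density_limits(self):
        assert lysis_rate(StrategyKind.PTL, 0.0, 0.0, P) == 0.0
        assert lysis_rate(StrategyKind.PTW, 0.0, 0.0, P) == pytest.approx(
            P.s_max / P.H)

    def test_density_splits_between_B_and_I(self):
        total = 3.7
        for strat in (StrategyKind.PTL, StrategyKind.PTW):
            assert lysis_rate(strat, total, 0.0, P) == pytest.approx(
                lysis_rate(strat, 1.2, total - 1.2, P))

    def test_ptl_increasing_ptw_decreasing(self):
        dens = np.linspace(0.0, 50.0, 150)
        ptl = np.array([lysis_rate(StrategyKind.PTL, d, 0.0, P) for d in dens])
        ptw = np.array([lysis_rate(StrategyKind.PTW, d, 0.0, P) for d in dens])
        assert (np.diff(ptl) > 0).all()
        assert (np.diff(ptw) < 0).all()

    @settings(derandomize=True, max_examples=200)
    @given(st.sampled_from(list(StrategyKind)),
           st.floats(0.0, 1e3), st.floats(0.0, 1e3))
    def test_bounded_by_smax_over_H(self, strat, B, I):
        s = lysis_rate(strat, B, I, P)
        assert 0.0 <= s <= P.s_max / min(1.0, P.H) + 1e-12


class TestGrowthSwitch:
    def test_lytic_never_grows(self):
        assert not growth_enabled(StrategyKind.LYTIC, 0.0, P)

    def test_ptl_lysogenic_when_rare(self):
        dens = 0.9 * switch_density(StrategyKind.PTL, P)
        s = lysis_rate(StrategyKind.PTL, dens, 0.0, P)
        assert growth_enabled(StrategyKind.PTL, s, P)

    def test_ptw_lysogenic_when_abundant(self):
        dens = 1.1 * switch_density(StrategyKind.PTW, P)
        s = lysis_rate(StrategyKind.PTW, dens, 0.0, P)
        assert growth_enabled(StrategyKind.PTW, s, P)

    def test_switch_densities_match_lysis_inversion(self):
        assert switch_density(StrategyKind.PTL, P) == pytest.approx(
            math.sqrt(0.0033 * 4.0 / (0.33 - 0.0033)), rel=1e-12)
        assert switch_density(StrategyKind.PTW, P) == pytest.approx(
            2.0 * math.sqrt(99.0), rel=1e-12)

    def test_rate_rule_equivalent_to_density_rule(self, rng):
        """Comparing the lysis rate to s_switch is the same as comparing the
        host density to the inverted switch density."""
        densities = rng.uniform(0.0, 60.0, size=1000)
        for strat in (StrategyKind.PTL, StrategyKind.PTW):
            d_star = switch_density(strat, P)
            for dens in densities:
                by_rate = growth_enabled(
                    strat, lysis_rate(strat, dens, 0.0, P), P)
                by_density = dens <= d_star if strat is StrategyKind.PTL \
                    else dens >= d_star
                assert by_rate == by_density


class TestTurnover:
    def test_constant_supply_limit(self):
        for t in (0.0, 3.7, 1e4):
            assert turnover_rate(t, P) == P.D

    def test_zero_phase(self):
        p = P.replace(a=0.5, T=720.0)
        assert turnover_rate(0.0, p) == pytest.approx(p.D)

    def test_quarter_period_peak(self):
        p = P.replace(a=0.5, T=720.0)
        assert turnover_rate(180.0, p) == pytest.approx(0.0625, abs=1e-12)

    def test_mean_over_period_is_D(self):
        p = P.replace(a=0.9, T=240.0)
        t = np.linspace(0.0, 240.0, 100_001)
        vals = [turnover_rate(v, p) for v in t]
        assert np.trapezoid(vals, t) / 240.0 == pytest.approx(p.D, rel=1e-6)
        assert min(vals) > 0.0

    def test_amplitude_ge_one_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(a=1.0)


class TestDerivatives:
    def test_washout_fixed_point(self):
        state = SystemState(0, 0, 0, 0, 0, 0, P.N0)
        for strat in StrategyKind:
            d = derivatives(0.0, state, strat, P).to_array()
            assert np.linalg.norm(d) < 1e-12

    def test_single_species_chemostat_fixed_point(self):
        # G(N*) = x gives N* = 1/(y-1); nutrient balance gives B* = D(N0-N*)/x
        N_star = 1.0 / (P.y1 - 1.0)
        B_star = P.D * (P.N0 - N_star) / P.x
        assert N_star == pytest.approx(0.153846, abs=1e-6)
        assert B_star == pytest.approx(3.7341297, abs=1e-6)
        state = SystemState(B1=B_star, B2=0, N=N_star)
        d = derivatives(0.0, state, StrategyKind.NONE, P).to_array()
        assert np.linalg.norm(d) < 1e-12

    def test_full_burst_cancels_shunt(self):
        p = P.replace(n=1.0)
        state = SystemState(0.5, 0.4, 0.3, 0.2, 0.1, 0.1, 1.5)
        d_on = derivatives(0.0, state, StrategyKind.LYTIC, p)
        d_off = derivatives(0.0, state, StrategyKind.LYTIC,
                            p.replace(shunt_enabled=False))
        assert d_on.N == pytest.approx(d_off.N, rel=1e-14)

    def test_zero_conversion_bookkeeping(self):
        """With c=0 phage loss via infection vanishes and the infected gain
        equals i*B*P exactly."""
        p = P.replace(c=0.0)
        state = SystemState(0.6, 0.3, 0.2, 0.1, 0.05, 0.02, 1.0)
        d = derivatives(0.0, state, StrategyKind.LYTIC, p)
        s = p.s_max
        # phage equation: production minus decay only
        assert d.P1 == pytest.approx(p.n * s * state.I1 - p.d * state.P1, rel=1e-12)
        # infected equation: plain mass-action gain (lytic: no growth term)
        gain = p.i_norm * state.B1 * state.P1
        assert d.I1 == pytest.approx(gain - p.x * state.I1 - s * state.I1, rel=1e-12)

    def test_autonomous_without_forcing(self):
        state = SystemState(0.8, 0.7, 0.2, 0.1, 0.01, 0.02, 1.2)
        for strat in StrategyKind:
            d1 = derivatives(0.0, state, strat, P).to_array()
            d2 = derivatives(9876.5, state, strat, P).to_array()
            np.testing.assert_array_equal(d1, d2)

    def test_none_strategy_freezes_infection(self):
        state = SystemState(0.8, 0.7, N=1.2)
        d = derivatives(0.0, state, StrategyKind.NONE, P)
        assert d.I1 == d.I2 == d.P1 == d.P2 == 0.0

    def test_small_negative_components_clamped(self):
        state = SystemState(0.8, -1e-12, 0.2, 0.1, 0.01, -1e-13, 1.2)
        d = derivatives(0.0, state, StrategyKind.LYTIC, P)
        clamped = SystemState(0.8, 0.0, 0.2, 0.1, 0.01, 0.0, 1.2)
        np.testing.assert_allclose(d.to_array(),
                                   derivatives(0.0, clamped, StrategyKind.LYTIC,
                                               P).to_array())

    def test_non_finite_state_rejected(self):
        state = SystemState(np.nan, 0.7, N=1.2)
        with pytest.raises(FloatingPointError):
            derivatives(0.0, state, StrategyKind.LYTIC, P)


class TestParamValidation:
    @pytest.mark.parametrize("bad", [
        dict(x=-0.1),
        dict(n=0.0),
        dict(n=1.5),
        dict(a=1.2),
        dict(y1=4.0, y2=7.5),        # slow grower may not outgrow the fast one
        dict(s_switch=0.5),          # switch above the maximum lysis rate
        dict(a=0.5, T=0.0),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelParams(**bad)

    def test_default_initial_state_none_has_no_infection(self):
        s = default_initial_state(StrategyKind.NONE, P)
        assert s.I1 == s.I2 == s.P1 == s.P2 == 0.0
        assert s.N == P.N0

    def test_default_initial_state_table_values(self):
        s = default_initial_state(StrategyKind.PTL, P)
        assert (s.B1, s.I1, s.P1) == (0.83, 0.17, 3.10e-4)
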