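"""Heat-balance plant: flux formulas, pad physics, integration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coopclim.config import DEFAULT_HOUSE, ExogenousSample, HouseConfig, VentilationCommand
from coopclim import plant


def make_exo(t0=20.0, ts=None, irradiance=0.0, tg=20.0, tn=None, tw=None, pad_open=False):
    return ExogenousSample(
        time=0.0, t0=t0, ts=t0 if ts is None else ts, irradiance=irradiance,
        floor_temp=tg, wall_inner=tn, wall_outer=tw, pad_open=pad_open,
    )


class TestFluxFormulas:
    @pytest.mark.parametrize(
        "ps,sw,irr,expected",
        [(0.64, 1491.0, 0.0, 0.0), (0.64, 1491.0, 500.0, 477120.0), (1.0, 1.0, 250.0, 250.0)],
    )
    def test_solar_gain(self, ps, sw, irr, expected):
        assert plant.solar_gain(ps, sw, irr) == pytest.approx(expected)

    def test_solar_gain_rejects_negative_irradiance(self):
        with pytest.raises(ValueError):
            plant.solar_gain(0.64, 1491.0, -1.0)

    @pytest.mark.parametrize(
        "m,y,ti,expected",
        [(1.0, 0.0, 20.0, 6.28), (16.0, 0.0, 20.0, 50.24), (0.0, 0.0, 35.0, 0.0)],
    )
    def test_total_heat_production(self, m, y, ti, expected):
        assert plant.total_heat_production(m, y, ti) == pytest.approx(expected)

    def test_metabolic_correction_is_unity_at_20C(self):
        # the thermoregulatory cubic vanishes exactly at the 20 degC reference
        base = 6.28 * 10.0**0.75
        assert plant.total_heat_production(10.0, 0.0, 20.0) == pytest.approx(base, rel=1e-12)

    def test_sensible_fraction_reference_values(self):
        assert plant.sensible_fraction(20.0) == pytest.approx(0.663728, abs=1e-9)
        assert plant.sensible_fraction(0.0) == pytest.approx(0.402, abs=1e-12)

    def test_sensible_fraction_clamped_at_extremes(self):
        assert 0.0 <= plant.sensible_fraction(80.0) <= 1.0
        assert plant.sensible_heat(0.0, 0.0, 35.0) == 0.0

    def test_negative_flock_mass_rejected(self):
        with pytest.raises(ValueError):
            plant.total_heat_production(-1.0, 0.0, 20.0)

    @pytest.mark.parametrize(
        "ti,tg,hg,sg,expected",
        [(28.0, 28.0, 6.0, 1500.0, 0.0), (28.0, 26.0, 6.0, 1500.0, 18000.0),
         (26.0, 28.0, 6.0, 1500.0, -18000.0)],
    )
    def test_floor_heat_loss(self, ti, tg, hg, sg, expected):
        assert plant.floor_heat_loss(ti, tg, hg, sg) == pytest.approx(expected)

    def test_envelope_heat_loss(self):
        assert plant.envelope_heat_loss(27.0, 17.0, 0.93, 920.0) == pytest.approx(8556.0)
        assert plant.envelope_heat_loss(20.0, 20.0, 0.93, 920.0) == 0.0
        one = plant.envelope_heat_loss(25.0, 15.0, 0.93, 920.0)
        assert plant.envelope_heat_loss(25.0, 15.0, 0.93, 1840.0) == pytest.approx(2 * one)


class TestCoolingPad:
    def test_closed_pad_passes_dry_bulb(self):
        assert plant.pad_outlet_temperature(30.0, 22.0, 1.5, 0.15, pad_open=False) == 30.0

    def test_zero_depression(self):
        assert plant.pad_outlet_temperature(25.0, 25.0, 2.0, 0.15, pad_open=True) == 25.0

    def test_reference_evaluation(self):
        # independent scalar evaluation of the decay factor
        expected = 22.0 + 8.0 * math.exp(-12.28305 * 1.5 ** (-0.30078) * 0.15)
        got = plant.pad_outlet_temperature(30.0, 22.0, 1.5, 0.15, pad_open=True)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_vanishing_velocity_saturates(self):
        assert plant.pad_outlet_temperature(30.0, 22.0, 0.0, 0.15, pad_open=True) == 22.0

    def test_wet_bulb_above_dry_bulb_rejected(self):
        with pytest.raises(ValueError):
            plant.pad_outlet_temperature(20.0, 22.0, 1.0, 0.15)

    @settings(derandomize=True, max_examples=200)
    @given(
        t0=st.floats(-15.0, 40.0),
        depression=st.floats(0.0, 15.0),
        v=st.floats(0.0, 30.0),
        h=st.floats(0.05, 0.3),
    )
    def test_outlet_bounded_by_wet_and_dry_bulb(self, t0, depression, v, h):
        ts = t0 - depression
        tc = plant.pad_outlet_temperature(t0, ts, v, h, pad_open=True)
        assert ts - 1e-9 <= tc <= t0 + 1e-9

    def test_literal_exponent_reading_is_selectable(self):
        # including rho*cp in the exponent drives the pad to full saturation
        tc = plant.pad_outlet_temperature(
            30.0, 22.0, 1.5, 0.15, pad_open=True, exponent_literal=True
        )
        assert tc == pytest.approx(22.0, abs=1e-6)


class TestVentilationSplit:
    @pytest.mark.parametrize(
        "l,lam,expected",
        [(10.0, 0.0, (0.0, 2.0)), (10.0, 1.0, (2.0, 0.0)), (10.0, 0.5, (1.0, 1.0))],
    )
    def test_split_velocities(self, l, lam, expected):
        assert plant.split_velocities(l, lam, 5.0, 5.0) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=200)
    @given(
        l=st.floats(0.0, 150.0),
        lam=st.floats(0.0, 1.0),
        a_pos=st.floats(0.5, 20.0),
        a_duct=st.floats(0.5, 20.0),
    )
    def test_flow_conservation(self, l, lam, a_pos, a_duct):
        v_pos, v_duct = plant.split_velocities(l, lam, a_pos, a_duct)
        assert a_pos * v_pos + a_duct * v_duct == pytest.approx(l, rel=1e-9, abs=1e-9)

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError):
            plant.split_velocities(10.0, 1.5, 5.0, 5.0)

    def test_ventilation_loss_closed_pad_hand_value(self):
        cfg = HouseConfig(air_density=1.2, air_cp=1006.0)
        exo = make_exo(t0=20.0, pad_open=False)
        cmd = VentilationCommand(flow=10.0, split=0.3)
        q_pos, q_duct = plant.ventilation_heat_loss(28.0, cmd, cfg, exo)
        assert q_pos == pytest.approx(28972.8)
        assert q_duct == pytest.approx(67603.2)

    def test_no_flow_no_loss(self):
        cmd = VentilationCommand(flow=0.0, split=0.5)
        exo = make_exo(t0=20.0, ts=15.0, pad_open=True)
        assert plant.ventilation_heat_loss(28.0, cmd, DEFAULT_HOUSE, exo) == (0.0, 0.0)

    def test_no_temperature_difference_no_loss(self):
        exo = make_exo(t0=28.0, pad_open=False)
        cmd = VentilationCommand(flow=10.0, split=0.3)
        assert plant.ventilation_heat_loss(28.0, cmd, DEFAULT_HOUSE, exo) == (0.0, 0.0)

    def test_loss_monotone_in_flow_with_closed_pad(self):
        exo = make_exo(t0=20.0, pad_open=False)
        losses = []
        for flow in np.linspace(1.0, 100.0, 12):
            q = plant.ventilation_heat_loss(
                28.0, VentilationCommand(flow=float(flow), split=0.3), DEFAULT_HOUSE, exo
            )
            losses.append(sum(q))
        assert all(b > a for a, b in zip(losses, losses[1:]))


class TestIntegration:
    def test_derivative_definitional_values(self):
        cfg = DEFAULT_HOUSE
        cap = cfg.thermal_capacity  # 1.2 * 6375 * 1006
        assert cap == pytest.approx(7.6959e6, rel=1e-4)
        budget = plant.HeatBudget(qs=cap, qc=0, qv_pos=0, qv_duct=0, qg=0, qw=0)
        assert plant.temperature_derivative(budget, cfg) == pytest.approx(1.0)
        budget = plant.HeatBudget(qs=-cap / 2, qc=0, qv_pos=0, qv_duct=0, qg=0, qw=0)
        assert plant.temperature_derivative(budget, cfg) == pytest.approx(-0.5)

    def test_net_identity(self):
        b = plant.HeatBudget(qs=5.0, qc=4.0, qv_pos=3.0, qv_duct=2.0, qg=1.0, qw=0.5)
        assert b.net == pytest.approx(5 + 4 - (3 + 2) - 1 - 0.5)

    def test_euler_step_matches_definition(self):
        cfg = DEFAULT_HOUSE
        exo = make_exo(t0=20.0, tg=25.0, tn=26.0, tw=20.0, pad_open=False)
        cmd = VentilationCommand(flow=40.0, split=0.2)
        s0 = plant.HouseState(ti=27.0)
        budget = plant.heat_budget(27.0, cmd, cfg, exo)
        expected = 27.0 + 60.0 * budget.net / cfg.thermal_capacity
        assert plant.step(s0, exo, cmd, cfg, dt=60.0).ti == pytest.approx(expected, rel=1e-14)

    def test_equilibrium_state_is_fixed_point(self):
        cfg = DEFAULT_HOUSE
        exo = make_exo(t0=20.0, tg=24.0, tn=25.0, tw=20.0, pad_open=False)
        cmd = VentilationCommand(flow=50.0, split=0.3)
        from scipy.optimize import brentq

        ti_star = brentq(
            lambda ti: plant.heat_budget(ti, cmd, cfg, exo).net, -30.0, 60.0, xtol=1e-10
        )
        s = plant.HouseState(ti=float(ti_star))
        assert plant.step(s, exo, cmd, cfg, dt=60.0).ti == pytest.approx(ti_star, abs=1e-6)

    def test_halved_step_converges(self):
        """Euler endpoint error shrinks ~linearly with dt (quarter-step oracle)."""
        cfg = DEFAULT_HOUSE
        exo = make_exo(t0=15.0, tg=24.0, tn=25.0, tw=15.0, pad_open=False)
        cmd = VentilationCommand(flow=80.0, split=0.4)

        def integrate(dt, n):
            s = plant.HouseState(ti=30.0)
            for _ in range(n):
                s = plant.step(s, exo, cmd, cfg, dt=dt)
            return s.ti

        ref = integrate(3.75, 160)  # quarter-quarter step reference
        err_60 = abs(integrate(60.0, 10) - ref)
        err_30 = abs(integrate(30.0, 20) - ref)
        assert err_30 < err_60
        assert err_60 < 0.1  # endpoint moves by O(dt) only

    def test_rk4_close_to_fine_euler(self):
        cfg = DEFAULT_HOUSE
        exo = make_exo(t0=15.0, tg=24.0, tn=25.0, tw=15.0, pad_open=False)
        cmd = VentilationCommand(flow=80.0, split=0.4)
        s_rk = plant.HouseState(ti=30.0)
        for _ in range(10):
            s_rk = plant.step(s_rk, exo, cmd, cfg, dt=60.0, method="rk4")
        s_fine = plant.HouseState(ti=30.0)
        for _ in range(600):
            s_fine = plant.step(s_fine, exo, cmd, cfg, dt=1.0)
        assert s_rk.ti == pytest.approx(s_fine.ti, abs=5e-3)

    def test_unknown_integrator_rejected(self):
        with pytest.raises(ValueError):
            plant.step(
                plant.HouseState(ti=20.0), make_exo(), VentilationCommand(0.0, 0.0),
                DEFAULT_HOUSE, dt=60.0, method="heun",
            )
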