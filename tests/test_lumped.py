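"""Heart chambers, valves, Starling resistors and pulmonary compartments."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hemonet.lumped as lp


@pytest.fixture(scope="module")
def heart():
    return lp.default_heart_params(period=0.9)


class TestElastance:
    def test_minimum_at_onset(self, heart):
        for name, cp in heart.chambers.items():
            assert heart.E_fw(name, cp.t_onset) == pytest.approx(cp.E_min)

    def test_maximum_attained(self, heart):
        t = np.linspace(0, heart.period, 20000, endpoint=False)
        for name, cp in heart.chambers.items():
            E = heart.E_fw(name, t)
            assert float(np.max(E)) == pytest.approx(cp.E_max, rel=1e-5)

    def test_shape_at_tau1(self, heart):
        cp = heart.chambers["LV"]
        k = lp.elastance_normalization(cp, heart.period)
        g2 = (cp.tau1 / cp.tau2) ** cp.m2
        expected = k * 0.5 / (1.0 + g2) + cp.E_min
        assert heart.E_fw("LV", cp.t_onset + cp.tau1) == pytest.approx(expected)

    def test_periodicity(self, heart):
        t = np.linspace(0, heart.period, 50)
        for name in heart.chambers:
            assert np.allclose(heart.E_fw(name, t),
                               heart.E_fw(name, t + 3 * heart.period))


class TestChamberPressures:
    def test_septal_symmetry(self, heart):
        E_LA, E_RA = heart.E_fw("LA", 0.3), heart.E_fw("RA", 0.3)
        s1 = lp.septal_elastance(E_LA, E_RA, heart.K_C_atria)
        s2 = lp.septal_elastance(E_RA, E_LA, heart.K_C_atria)
        assert s1 == s2

    def test_large_septal_constant_decouples_chambers(self):
        hp = lp.default_heart_params()
        hp_stiff = lp.HeartParams(chambers=hp.chambers,
                                  pericardium=hp.pericardium,
                                  K_C_atria=1e9, K_C_ventricles=1e9,
                                  period=hp.period)
        vols = {"RA": 50.0, "RV": 110.0, "LA": 50.0, "LV": 110.0}
        zero = {c: 0.0 for c in lp.CHAMBERS}
        p, p_pc = lp.chamber_pressures(hp_stiff, 0.25, vols, zero)
        for c in lp.CHAMBERS:
            cp = hp.chambers[c]
            E_fw = hp_stiff.E_fw(c, 0.25)
            expected = p_pc + E_fw * (vols[c] - cp.V0)
            assert p[c] == pytest.approx(expected, rel=1e-6)

    def test_pericardium_reference_volume(self):
        pc = lp.PericardiumParams()
        total = pc.V0_pc - pc.V_mio - pc.V_pcf
        assert lp.pericardial_pressure(total, pc) == pytest.approx(pc.K_pc)

    def test_native_elastance_harmonic_form(self):
        E = lp.native_elastance(100.0, 300.0, mu_AV=0.0, q_V=123.0)
        assert E == pytest.approx(100.0 * 300.0 / 400.0)


class TestValves:
    def test_effective_area_endpoints(self):
        p = lp.ValveParams(l_eff=1.0, A_eff_max=5.0, A_eff_min=0.5)
        assert lp.effective_area(1.0, p) == 5.0
        assert lp.effective_area(0.0, p) == 0.5

    def test_sealed_valve_area_floored(self):
        p = lp.ValveParams(l_eff=1.0, A_eff_max=5.0, A_eff_min=0.0)
        assert lp.effective_area(0.0, p) == pytest.approx(5.0e-6)

    def test_steady_flow_is_bernoulli_limit(self):
        p = lp.ValveParams(l_eff=1.0, A_eff_max=4.0)
        state = lp.ValveState(zeta=1.0, q=0.0)
        dp = 2.0e4
        for _ in range(30000):
            q = lp.valve_flow_step(state, dp, 0.0, 1e-4, p, rho=1.04)
            state = lp.ValveState(zeta=1.0, q=q)
        B = 1.04 / (2.0 * 16.0)
        assert state.q == pytest.approx(math.sqrt(dp / B), rel=1e-6)

    def test_hysteresis_band_freezes_state(self):
        p = lp.ValveParams(l_eff=1.0, A_eff_max=4.0, dp_open=500.0,
                           dp_close=-500.0)
        z = lp.valve_state_step(0.4, 100.0, 1e-3, p)
        assert z == 0.4

    def test_opening_and_closing_directions(self):
        p = lp.ValveParams(l_eff=1.0, A_eff_max=4.0)
        assert lp.valve_state_step(0.5, 1000.0, 1e-3, p) > 0.5
        assert lp.valve_state_step(0.5, -1000.0, 1e-3, p) < 0.5

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(z=st.floats(0.0, 1.0), dp=st.floats(-1e5, 1e5),
           dt=st.floats(1e-5, 2e-3))
    def test_state_stays_in_unit_interval(self, z, dp, dt):
        p = lp.ValveParams(l_eff=1.0, A_eff_max=4.0)
        assert 0.0 <= lp.valve_state_step(z, dp, dt, p) <= 1.0

    def test_closed_valve_flow_decays(self):
        p = lp.ValveParams(l_eff=1.0, A_eff_max=4.0)
        state = lp.ValveState(zeta=0.0, q=5.0)
        qs = [state.q]
        for _ in range(50):
            q = lp.valve_flow_step(state, 0.0, 0.0, 1e-4, p, rho=1.04)
            state = lp.ValveState(zeta=0.0, q=q)
            qs.append(q)
        assert all(b < a for a, b in zip(qs, qs[1:]))


class TestStarling:
    def test_open_state_transparent(self):
        assert lp.starling_effective_downstream(9000.0, 15000.0, 1.0) == 9000.0

    def test_collapsed_state_uses_external_pressure(self):
        """Waterfall: with the segment collapsed, the driving pressure is
        the external (intracranial) one, independent of downstream."""
        for p_down in (2000.0, 5000.0, 8000.0):
            assert lp.starling_effective_downstream(p_down, 15000.0, 0.0) \
                == 15000.0

    def test_state_opens_when_downstream_exceeds_external(self):
        p = lp.StarlingParams(l_eff=1.0, A_eff=0.3)
        state = lp.ValveState(zeta=0.2, q=0.0)
        for _ in range(2000):
            state = lp.starling_step(state, 16000.0, 14000.0, 9000.0,
                                     1e-3, p, 1.04)
        assert state.zeta > 0.999

    def test_orifice_fixed_regardless_of_state(self):
        p = lp.StarlingParams(l_eff=1.0, A_eff=0.3)
        vp = p.as_valve()
        assert lp.effective_area(0.0, vp) == lp.effective_area(1.0, vp) == 0.3


class TestPulmonary:
    def test_reference_pressure_at_zero_volume(self):
        params = lp.default_pulmonary_params()
        state = lp.PulmonaryState(V={"pua": 0.0, "puc": 0.0, "puv": 0.0},
                                  q={"pua": 0.0, "puc": 0.0, "puv": 0.0})
        c = params.compartments["pua"]
        assert lp.pulmonary_pressure("pua", state, params, 0.0) \
            == pytest.approx(c.E0 * c.V0)

    def test_steady_state_chain(self):
        """Driven at constant inflow with fixed left-atrial pressure, the
        chain settles to equal flows and resistive pressure drops."""
        params = lp.default_pulmonary_params()
        state = lp.PulmonaryState(V={"pua": 60.0, "puc": 98.0, "puv": 108.0},
                                  q={"pua": 0.0, "puc": 0.0, "puv": 0.0})
        q_pv, p_LA = 80.0, 1.1e4
        for _ in range(200000):
            state, p = lp.pulmonary_step(state, p_LA, q_pv, 5e-4, params)
        for name in lp.PULMONARY_COMPARTMENTS:
            assert state.q[name] == pytest.approx(q_pv, rel=1e-6)
        c = params.compartments["pua"]
        assert p["pua"] - p["puc"] == pytest.approx(c.R * q_pv, rel=1e-5)

    def test_total_volume_rate(self):
        params = lp.default_pulmonary_params()
        state = lp.PulmonaryState(V={"pua": 60.0, "puc": 98.0, "puv": 108.0},
                                  q={"pua": 10.0, "puc": 20.0, "puv": 30.0})
        dt, q_pv = 1e-3, 50.0
        new, _ = lp.pulmonary_step(state, 1.1e4, q_pv, dt, params)
        dV = sum(new.V.values()) - sum(state.V.values())
        assert dV == pytest.approx(dt * (q_pv - state.q["puv"]), rel=1e-12)
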