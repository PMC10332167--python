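"""Peripheral and coronary bed derivation rules and dynamics; ICP model."""

import math

import numpy as np
import pytest

import hemonet.beds as beds
import hemonet.mechanics as mech
import hemonet.network as nw


@pytest.fixture(scope="module")
def cc_beds(cc_net):
    return beds.derive_peripheral_parameters(
        cc_net, mech.VenousParamRules(), rho=1.04,
        coronary_territories={"coronary"}, intracranial_veins={6})


class TestCubeRule:
    def test_equal_radii_split_evenly(self):
        R = beds.cube_rule_split(1000.0, {1: 0.3, 2: 0.3})
        assert R[1] == R[2]
        assert 1.0 / R[1] + 1.0 / R[2] == pytest.approx(1e-3)

    def test_two_to_one_radii_give_eight_to_one_conductance(self):
        R = beds.cube_rule_split(1000.0, {1: 0.4, 2: 0.2})
        assert R[2] / R[1] == pytest.approx(8.0, rel=1e-12)


class TestPeripheralDerivation:
    def test_proximal_resistance_fraction(self, cc_net, cc_beds):
        for t, bed in cc_beds.items():
            for a in bed.arteries:
                assert bed.R_a[a] == pytest.approx(
                    0.15 * cc_net.terminals[a].R_t)

    def test_equivalent_av_resistance(self, cc_net, cc_beds):
        """Parallel combination of each artery's AV resistances equals
        0.85 R_t, network-wide."""
        for t, bed in cc_beds.items():
            for a in bed.arteries:
                g = sum(1.0 / R for (ai, _), R in bed.R_av.items() if ai == a)
                assert 1.0 / g == pytest.approx(
                    0.85 * cc_net.terminals[a].R_t, rel=1e-12)

    def test_venous_resistance_is_characteristic_impedance(self, cc_net, cc_beds):
        rules = mech.VenousParamRules()
        bed = next(b for b in cc_beds.values() if 10 in b.veins)
        ves = cc_net.vessels[10]
        A_hat = math.pi * ves.radius_prox ** 2
        c, _ = mech.venous_celerity_and_stiffness(
            ves.radius_at(0.5), rules, 1.04, 10.0, -1.5)
        assert bed.R_v[10] == pytest.approx(1.04 * c / A_hat, rel=1e-12)

    def test_residual_compliance_fully_distributed(self, cc_beds):
        """Non-coronary, extracranial venular compliances sum to C_v,res."""
        got = sum(bed.distal[v].C for bed in cc_beds.values()
                  for v in bed.veins if v in (10, 11))
        # C_v,res = C_v,data here (C_v_1D = 0 in this derivation call)
        assert got == pytest.approx(beds.C_V_DATA_DEFAULT, rel=1e-12)

    def test_overcompliant_network_rejected(self, cc_net):
        with pytest.raises(ValueError, match="residual venous compliance"):
            beds.derive_peripheral_parameters(
                cc_net, mech.VenousParamRules(), 1.04,
                C_v_data=1e-6, C_v_1D=2e-6)


class TestPeripheralDynamics:
    def test_equal_pressures_give_zero_av_flow(self, cc_beds):
        import copy
        bed = copy.deepcopy(next(b for b in cc_beds.values() if 10 in b.veins))
        for c in list(bed.proximal.values()) + list(bed.distal.values()):
            c.V = c.C * 5.0e4
            c.p_ext = 0.0
        assert all(abs(q) < 1e-12 for q in bed.av_flows().values())

    def test_multi_feeder_vein_sums_terms(self, cc_beds):
        """A venular compartment fed by two arteries receives the sum of
        both AV flows (the many-to-many connectivity pattern)."""
        import copy
        bed = copy.deepcopy(next(b for b in cc_beds.values() if 10 in b.veins))
        for c in bed.proximal.values():
            c.V = c.C * 8.0e4
        for c in bed.distal.values():
            c.V = c.C * 1.0e4
        expected = sum((bed.proximal[a].pressure() - bed.distal[10].pressure())
                       / bed.R_av[(a, 10)] for a in (3, 4))
        assert bed.q_in_venous(10) == pytest.approx(expected, rel=1e-12)

    def test_volume_bookkeeping(self, cc_beds):
        import copy
        bed = copy.deepcopy(next(b for b in cc_beds.values() if 10 in b.veins))
        for c in bed.proximal.values():
            c.V = c.C * 8.0e4
        for c in bed.distal.values():
            c.V = c.C * 1.0e4
        V0 = sum(c.V for c in bed.proximal.values()) \
            + sum(c.V for c in bed.distal.values())
        q_in = {a: 2.0 for a in bed.arteries}
        q_out = {v: 1.0 for v in bed.veins}
        dt = 1e-3
        beds.step_peripheral(bed, q_in, q_out, dt)
        V1 = sum(c.V for c in bed.proximal.values()) \
            + sum(c.V for c in bed.distal.values())
        assert V1 - V0 == pytest.approx(
            dt * (sum(q_in.values()) - sum(q_out.values())), rel=1e-10)


class TestCoronaryDerivation:
    def test_layer_volume_split(self):
        split = beds.layer_split(2.80)
        assert split["sub-endo"] == pytest.approx(1.00)
        assert split["midwall"] == pytest.approx(0.93)
        assert split["sub-epi"] == pytest.approx(0.87)

    def test_parallel_resistance_split(self):
        R = beds.parallel_layer_resistances(1.0)
        assert R["sub-epi"] == pytest.approx(23.0 / 3.0)
        assert R["midwall"] == pytest.approx(4.6)
        assert R["sub-endo"] == pytest.approx(23.0 / 15.0)
        g = sum(1.0 / r for r in R.values())
        assert 1.0 / g == pytest.approx(1.0, rel=1e-12)

    def test_series_resistance_split(self):
        R = beds.series_split(2.7)
        assert R[1] == pytest.approx(1.2)
        assert R["m"] == pytest.approx(1.0)
        assert R[2] == pytest.approx(0.5)

    def test_perfusion_volume_rate(self):
        # V = V_perf * rho_myo * eta_1 / 100 g
        assert 100.0 * beds.RHO_MYO * beds.ETA[1] / 100.0 == pytest.approx(2.625)

    def test_network_wide_ratios(self, cc_net, cc_beds):
        R_av = {}
        for bed in cc_beds.values():
            R_av.update(bed.R_av)
        cor = beds.derive_coronary_parameters(cc_net, R_av)
        assert len(cor) == 1
        cb = cor[(5, 13)]
        for i in (1, 2):
            assert cb.V0[(i, "midwall")] / cb.V0[(i, "sub-endo")] \
                == pytest.approx(0.93)
            assert cb.V0[(i, "sub-epi")] / cb.V0[(i, "sub-endo")] \
                == pytest.approx(0.87)
        tot = {lam: sum(cb.R0[(j, lam)] for j in (1, "m", 2))
               for lam in beds.LAYERS}
        assert tot["midwall"] / tot["sub-epi"] == pytest.approx(0.6)
        assert tot["sub-endo"] / tot["sub-epi"] == pytest.approx(0.2)
        for lam in beds.LAYERS:
            assert cb.R0[(1, lam)] / cb.R0[("m", lam)] == pytest.approx(1.2)
            assert cb.R0[(2, lam)] / cb.R0[("m", lam)] == pytest.approx(0.5)
        # parallel combination anchored to the AV resistance
        g = sum(1.0 / tot[lam] for lam in beds.LAYERS)
        assert 1.0 / g == pytest.approx(R_av[(5, 13)], rel=1e-12)


class TestCoronaryDynamics:
    def _bed(self, cc_net, cc_beds):
        R_av = {}
        for bed in cc_beds.values():
            R_av.update(bed.R_av)
        return beds.derive_coronary_parameters(cc_net, R_av)[(5, 13)]

    def test_reference_volumes_give_nominal_resistances(self, cc_net, cc_beds):
        cb = self._bed(cc_net, cc_beds)
        R = cb.resistances()
        for k, v in R.items():
            assert v == pytest.approx(cb.R0[k], rel=1e-12)

    def test_halved_volume_quadruples_resistance(self, cc_net, cc_beds):
        cb = self._bed(cc_net, cc_beds)
        cb.V[(1, "midwall")] = 0.5 * cb.V0[(1, "midwall")]
        R = cb.resistances()
        assert R[(1, "midwall")] == pytest.approx(
            4.0 * cb.R0[(1, "midwall")], rel=1e-12)

    def test_middle_resistance_interpolation(self, cc_net, cc_beds):
        cb = self._bed(cc_net, cc_beds)
        cb.V[(2, "sub-epi")] = 0.5 * cb.V0[(2, "sub-epi")]
        R = cb.resistances()
        assert R[("m", "sub-epi")] == pytest.approx(
            1.75 * cb.R0[("m", "sub-epi")], rel=1e-12)


class TestIntramyocardialPressure:
    P = {"LV": 1.5e5, "RV": 3.0e4, "LA": 1.0e4, "RA": 8.0e3}
    V = {"LV": 100.0, "RV": 100.0, "LA": 50.0, "RA": 50.0}
    V0 = {"LV": 10.0, "RV": 10.0, "LA": 3.0, "RA": 3.0}

    def test_cep_collapses_when_pressures_match(self):
        for lam in beds.LAYERS:
            assert beds.cavity_induced_pressure(lam, 5e4, 5e4) == 5e4

    def test_subendo_cep_weight(self):
        p_pc = 2000.0
        cep = beds.cavity_induced_pressure("sub-endo", self.P["LV"], p_pc)
        assert cep == pytest.approx(p_pc + 5.0 / 6.0 * (self.P["LV"] - p_pc))

    def test_sip_vanishes_at_reference_volume(self):
        assert beds.shortening_induced_pressure(1e5, 10.0, 10.0) == 0.0

    def test_sip_clamp_bounds_pim(self):
        p_im = beds.intramyocardial_pressure(
            "LV-fw", "sub-endo", self.P, self.V, self.V0, p_pc=2000.0)
        cep = beds.cavity_induced_pressure("sub-endo", self.P["LV"], 2000.0)
        assert p_im == pytest.approx(cep + 0.5 * self.P["LV"])

    def test_verbatim_sip_available(self):
        p_im = beds.intramyocardial_pressure(
            "LV-fw", "sub-endo", self.P, self.V, self.V0, p_pc=2000.0,
            sip_cap=None)
        sip = beds.ALPHA_SIP * self.P["LV"] * (self.V["LV"] - self.V0["LV"])
        cep = beds.cavity_induced_pressure("sub-endo", self.P["LV"], 2000.0)
        assert p_im == pytest.approx(cep + sip)

    def test_septum_outer_pressure_is_rv(self):
        p_im = beds.intramyocardial_pressure(
            "IVS", "sub-epi", self.P, self.V, self.V0, p_pc=2000.0)
        cep = beds.cavity_induced_pressure("sub-epi", self.P["LV"], self.P["RV"])
        assert p_im == pytest.approx(cep + 0.5 * self.P["LV"])


class TestICP:
    def test_constant_without_volume_change(self):
        s = beds.ICPState()
        s2 = beds.icp_step(s, 0.0, 1e-3)
        assert s2.p == s.p

    def test_default_initial_condition(self):
        assert beds.ICPState().p == pytest.approx(14665.42)
        assert beds.ICPState().p / mech.MMHG == pytest.approx(11.0, abs=0.01)

    def test_exponential_closed_form_with_dt_refinement(self):
        """Under a prescribed cerebral volume ramp, p(t) converges to
        p(0) exp(k dV) as dt -> 0."""
        dV_total, T = 2.0, 1.0
        exact = beds.P_ICP_INITIAL * math.exp(0.15 * dV_total)
        errs = []
        for n in (100, 1000, 10000):
            s = beds.ICPState()
            dt = T / n
            for _ in range(n):
                s = beds.icp_step(s, dV_total / T, dt)
            errs.append(abs(s.p - exact) / exact)
        assert errs[2] < errs[1] < errs[0]
        assert errs[2] < 1e-4

    def test_nonpositive_pressure_rejected(self):
        with pytest.raises(ValueError):
            beds.ICPState(p=-1.0)
        s = beds.ICPState(p=10.0)
        with pytest.raises(ValueError):
            beds.icp_step(s, -1e9, 1.0)
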