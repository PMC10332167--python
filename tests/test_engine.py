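"""Closed-loop engine: assembly, stretched-volume enforcement, conservation
audits, determinism and periodicity."""

import numpy as np
import pytest

import hemonet.engine as eng
import hemonet.network as nw
import hemonet.solver as slv


class TestAssembly:
    def test_minimal_composition(self, minimal_net):
        sim = eng.assemble(minimal_net, eng.SimulationConfig(V_set=None))
        assert len(sim.grids) == 4
        assert len(sim.beds) == 1
        assert set(sim.valves) == {"av", "mv", "pv", "tv"}
        assert set(sim.pulm.V) == {"pua", "puc", "puv"}
        assert set(sim.heart.volumes) == {"RA", "RV", "LA", "LV"}

    def test_cerebral_coronary_has_icp_bound_starling(self, cc_net):
        sim = eng.assemble(cc_net, eng.SimulationConfig(V_set=None))
        kinds = [el["spec"].kind for el in sim.elements]
        assert nw.ElementKind.STARLING_RESISTOR in kinds
        # intracranial vessels see the ICP as external pressure
        for vid in sim.intracranial:
            assert sim.grids[vid].p_ext == sim.icp.p
        # dural sinus stays at atmospheric reference
        assert sim.grids[7].p_ext == 0.0
        assert sim.coronary, "coronary beds derived"

    def test_short_vessel_single_cell(self, minimal_net):
        import copy
        net = copy.deepcopy(minimal_net)
        net.vessels[1].length = 0.4
        sim = eng.assemble(net, eng.SimulationConfig(V_set=None))
        assert sim.grids[1].n_cells == 1

    def test_every_end_has_role(self, cc_net):
        sim = eng.assemble(cc_net, eng.SimulationConfig(V_set=None))
        for vid in cc_net.vessels:
            assert (vid, -1) in sim.roles and (vid, +1) in sim.roles

    def test_schedule_macro_capped(self, cc_net):
        sim = eng.assemble(cc_net, eng.SimulationConfig(V_set=None))
        assert sim.macro_dt <= sim.cfg.solver.dt_max
        for vid, (n, dtk) in sim.schedule.items():
            assert n * dtk == pytest.approx(sim.macro_dt)


class TestStretchedVolume:
    def test_matched_set_point_gives_zero_source(self, minimal_net):
        probe = eng.assemble(minimal_net, eng.SimulationConfig(V_set=None))
        cfg = eng.SimulationConfig(V_set=probe.V_stretched0)
        sim = eng.assemble(minimal_net, cfg)
        sim.enforce_stretched_volume()
        assert sim.injection_rate == pytest.approx(0.0, abs=1e-12)

    def test_thirty_ml_gives_ten_per_second(self, minimal_net):
        probe = eng.assemble(minimal_net, eng.SimulationConfig(V_set=None))
        cfg = eng.SimulationConfig(V_set=probe.V_stretched0 + 30.0)
        sim = eng.assemble(minimal_net, cfg)
        sim.enforce_stretched_volume()
        assert sim.injection_rate == pytest.approx(10.0)
        assert sim.injection_until == pytest.approx(3.0)

    def test_audit_counts_all_pools(self, minimal_run):
        sim, _ = minimal_run
        total = sim.stretched_volume()
        assert total > 0
        assert sim.total_blood_volume() > total  # unstressed volume exists


class TestRunLoop:
    def test_volume_conservation_per_cycle(self, minimal_run):
        _, rec = minimal_run
        v = rec.audit["volume"]
        for cyc in range(1, rec.n_complete_cycles()):
            i0, i1 = rec.cycle_indices(cyc)
            assert abs(v[i1 - 1] - v[i0]) / v[i0] < 1e-3

    def test_junction_invariants_every_sample(self, minimal_run):
        _, rec = minimal_run
        assert rec.audit["junction_mass"].max() < 1e-9
        assert rec.audit["junction_spread"].max() < 1e-9

    def test_record_structure(self, minimal_run):
        _, rec = minimal_run
        assert rec.n_complete_cycles() == 3
        assert set(rec.monitors)
        for d in rec.monitors.values():
            assert len(d["p"]) == len(rec.t)
        assert "p_LV" in rec.lumped and "q_av" in rec.lumped

    def test_physiological_pressures(self, minimal_run):
        from hemonet.mechanics import MMHG
        _, rec = minimal_run
        i0, i1 = rec.cycle_indices(2)
        p_lv = rec.lumped["p_LV"][i0:i1] / MMHG
        assert 60.0 < p_lv.max() < 220.0
        assert rec.lumped["q_av"][i0:i1].mean() > 20.0

    def test_determinism(self, minimal_net):
        recs = []
        for _ in range(2):
            sim = eng.assemble(minimal_net, eng.SimulationConfig(V_set=None))
            recs.append(sim.run(n_cycles=1, stop_on_periodic=False))
        a, b = recs
        assert np.array_equal(a.t, b.t)
        for k in a.monitors:
            assert np.array_equal(a.monitors[k]["p"], b.monitors[k]["p"])
        for k in a.lumped:
            assert np.array_equal(a.lumped[k], b.lumped[k])


class TestYamlConfig:
    def test_round_trip_fields(self, tmp_path):
        p = tmp_path / "run.yaml"
        p.write_text(
            "period: 0.8\n"
            "V_set: 1500.0\n"
            "solver: {CFL: 0.5, limiter: minmod}\n"
            "fluid: {mu: 0.035}\n"
            "venous: {c_min: 120.0}\n")
        cfg = eng.config_from_yaml(p)
        assert cfg.period == 0.8
        assert cfg.V_set == 1500.0
        assert cfg.solver.CFL == 0.5 and cfg.solver.limiter == "minmod"
        assert cfg.fluid.mu == 0.035
        assert cfg.venous_rules.c_min == 120.0

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "run.yaml"
        p.write_text("not_a_key: 1\n")
        with pytest.raises(ValueError, match="unknown config key"):
            eng.config_from_yaml(p)


class TestWaveformRecord:
    def test_hdf5_roundtrip(self, minimal_run, tmp_path):
        _, rec = minimal_run
        p = tmp_path / "rec.h5"
        rec.to_hdf5(p)
        rec2 = eng.WaveformRecord.from_hdf5(p)
        assert np.array_equal(rec.t, rec2.t)
        assert rec.cycle_starts == list(rec2.cycle_starts)
        for k in rec.monitors:
            assert np.array_equal(rec.monitors[k]["q"], rec2.monitors[k]["q"])


class TestPeriodicityCheck:
    def _synthetic(self, scale_last=1.0):
        T, n = 1.0, 100
        t = np.arange(3 * n) * (T / n)
        p = 1.0e5 + 2.0e4 * np.sin(2 * np.pi * t)
        p[2 * n:] *= scale_last
        rec = eng.WaveformRecord(t=t, monitors={"m": {"p": p, "q": p, "A": p}},
                                 cycle_starts=[0, n, 2 * n], period=T)
        return rec

    def test_identical_cycles_give_zero(self):
        assert eng.periodicity_check(self._synthetic(1.0)) < 1e-12

    def test_scaled_cycle_gives_epsilon(self):
        eps = 1e-3
        val = eng.periodicity_check(self._synthetic(1.0 + eps), k=2)
        # relative L2 of eps*p against p: close to eps
        assert val == pytest.approx(eps, rel=0.05)

    def test_requires_two_cycles(self):
        rec = eng.WaveformRecord(t=np.arange(10.0), monitors={},
                                 cycle_starts=[0], period=1.0)
        with pytest.raises(ValueError):
            eng.periodicity_check(rec)
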