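import logging

import numpy as np
import pytest

import hemonet.engine as eng
import hemonet.mechanics as mech
import hemonet.network as nw
import hemonet.solver as slv

logging.getLogger("hemonet").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def fluid():
    return mech.FluidParams()


@pytest.fixture(scope="session")
def minimal_net():
    return nw.build_fixture_network("minimal", 1)


@pytest.fixture(scope="session")
def cc_net():
    return nw.build_fixture_network("cerebral_coronary", 1)


def make_artery_grid(R0=0.5, L=10.0, n=10, mu=0.04, Km_scale=1.0):
    w = mech.with_km_scaled(mech.make_arterial_wall(R0), Km_scale)
    wf = slv.ArterialWallField([w] * n)
    return slv.VesselGrid(wf, length=L, rho=1.04, mu=mu)


def make_vein_grid(R0=0.4, L=10.0, n=10, mu=0.04, dural=False):
    rules = mech.VenousParamRules()
    w = mech.make_venous_wall(R0, R0, rules, 1.04, dural_sinus=dural)
    wf = slv.VenousWallField([w] * n)
    return slv.VesselGrid(wf, length=L, rho=1.04, mu=mu)


@pytest.fixture(scope="session")
def minimal_run(minimal_net):
    """Short closed-loop run of the minimal fixture, shared across tests."""
    sim = eng.assemble(minimal_net, eng.SimulationConfig(V_set=None))
    rec = sim.run(n_cycles=3, stop_on_periodic=False)
    return sim, rec


@pytest.fixture
def rng():
    return np.random.default_rng(42)
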