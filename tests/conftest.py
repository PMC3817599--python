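import numpy as np
import pytest

import gliosim as gs
from gliosim.morphology import Compartment, Morphology


@pytest.fixture(scope="session")
def ca3_morph():
    return gs.build_morphology("CA3")


@pytest.fixture(scope="session")
def ca1_morph():
    return gs.build_morphology("CA1")


@pytest.fixture(scope="session")
def ca3_rest(ca3_morph):
    return gs.resting_state(ca3_morph)


@pytest.fixture(scope="session")
def ca1_rest(ca1_morph):
    return gs.resting_state(ca1_morph)


def passive_pair(g_leak=0.1, length=100.0, diameter=10.0):
    """Two passive compartments (leak only) in series."""
    c0 = Compartment(0, None, length, diameter, "soma",
                     channel_densities={"leak": g_leak})
    c1 = Compartment(1, 0, length, diameter, "apical_dendrite",
                     channel_densities={"leak": g_leak})
    return Morphology("custom", [c0, c1])


@pytest.fixture(scope="session")
def passive_two_comp():
    return passive_pair()


@pytest.fixture(scope="session")
def ca3_burst_run():
    """Isolated CA3 cell, 0.6 nA somatic drive, 10 s (shared across tests)."""
    cfg = gs.NetworkConfig(scenario="no_astro", n_ca1=0, duration_s=10.0)
    return gs.simulate(cfg)


@pytest.fixture(scope="session")
def no_astro_run():
    """Full network without astrocyte, 20 s."""
    cfg = gs.NetworkConfig(scenario="no_astro", duration_s=20.0)
    return gs.simulate(cfg)


@pytest.fixture(scope="session")
def astro_on_run():
    """Full tripartite network, 20 s."""
    cfg = gs.NetworkConfig(scenario="astro_on", duration_s=20.0)
    return gs.simulate(cfg)


@pytest.fixture(scope="session")
def astro_subsystem_run():
    """CA3 + astrocyte subsystem (no CA1 cells), 12 s."""
    cfg = gs.NetworkConfig(scenario="astro_on", n_ca1=0, duration_s=12.0)
    return gs.simulate(cfg)


@pytest.fixture(scope="session")
def epileptiform_run():
    """Doubled-eNMDAR network over a window holding one Ca2+ epoch, 18 s."""
    cfg = gs.NetworkConfig(scenario="epileptiform", duration_s=18.0)
    return gs.simulate(cfg)


@pytest.fixture(scope="session")
def clamp_run():
    """Ca2+-clamp control (clamp at 100 nM, conductance doubled), 20 s."""
    cfg = gs.NetworkConfig(scenario="ca_clamp_control", duration_s=20.0)
    return gs.simulate(cfg)
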