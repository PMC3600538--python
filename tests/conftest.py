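import numpy as np
import pytest
from hypothesis import settings

import neurosim as ns

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def fork_small():
    """Fork: 10-segment trunk (soma first) with two 5-segment branches."""
    return ns.make_fork(10, 5)


@pytest.fixture
def btree5():
    """Soma plus a full binary tree of depth 5 (32 segments)."""
    return ns.make_binary_tree(5)


@pytest.fixture
def cable8():
    return ns.make_cable(8)


@pytest.fixture
def passive_params():
    return ns.BiophysParams()


@pytest.fixture
def single_compartment():
    """One passive compartment plus the constants of its analytic solution."""
    m = ns.make_cable(1, mech="pas")
    p = ns.BiophysParams()
    area = m.area_um2[0]
    G = p.g_pas * area * 1e-2   # uS
    C = p.Cm * area * 1e-5      # nF
    return m, p, G, C


def random_physical_system(n, seed, mech="mixed"):
    """Assembled backward-Euler system on a random tree with random but
    physical parameters (guaranteed diagonally dominant)."""
    rng = np.random.default_rng(seed)
    m = ns.make_random_tree(n, rng, mech=mech)
    p = ns.BiophysParams(Ra=float(rng.uniform(50, 300)),
                         Cm=float(rng.uniform(0.5, 2.0)))
    v = rng.uniform(-90.0, 40.0, n)
    gates = ns.GateState.steady(rng.uniform(-90.0, 40.0, n))
    i_stim = rng.uniform(-1.0, 1.0, n)
    dt = float(rng.choice([0.01, 0.1, 1.0]))
    sys_ = ns.assemble_system(m, p, gates, v, i_stim, dt)
    return m, sys_
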