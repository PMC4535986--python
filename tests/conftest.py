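"""Shared fixtures: packaged E. coli set, solved balances, synthetic fixtures."""

import numpy as np
import pytest

from elokin.balance import solve_self_consistent
from elokin.fixtures import generate_fixture
from elokin.io import ecoli_defaults


@pytest.fixture(scope="session")
def ecoli_232():
    """Packaged synthetic E. coli set at growth rate 2.5/h, 2-3-2 release."""
    return ecoli_defaults(2.5, "2-3-2")


@pytest.fixture(scope="session")
def ecoli_212():
    return ecoli_defaults(2.5, "2-1-2")


@pytest.fixture(scope="session")
def solution_232(ecoli_232):
    m, kp, rp, cs = ecoli_232
    return solve_self_consistent(cs, kp, rp, m)


@pytest.fixture(scope="session")
def solution_212(ecoli_212):
    m, kp, rp, cs = ecoli_212
    return solve_self_consistent(cs, kp, rp, m)


@pytest.fixture
def small_fixture():
    """Cheap synthetic fixture (few jumps per cycle) for stochastic tests."""
    return generate_fixture(1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
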