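"""Shared fixtures.

The five full loading-case runs and the L1 load sweep are expensive
(tens of seconds each), so they are computed once per session and shared
between the behavioural unit tests and the acceptance tests.
"""

import numpy as np
import pytest

import spinectrl as sc


@pytest.fixture(scope="session")
def case_results():
    """Converged full-horizon runs of the five built-in loading cases."""
    return {c: sc.run_case(c) for c in range(1, 6)}


@pytest.fixture(scope="session")
def sweep_table():
    """Steady-state muscle forces for L1 loads 150-750 N (case-2 base)."""
    return sc.run_load_sweep(2, [150.0, 350.0, 550.0, 750.0])


@pytest.fixture(scope="session")
def equilibrium_solutions():
    return {c: sc.solve_follower_load(c) for c in range(1, 6)}


@pytest.fixture()
def geometry():
    return sc.build_geometry()
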