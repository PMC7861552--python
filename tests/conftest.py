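"""Shared fixtures.

The expensive paced simulations used by the acceptance tests are session
scoped and cached so one 30-s depolarized run serves every criterion that
measures it.
"""

from __future__ import annotations

import numpy as np
import pytest

from mitoca import CellParams, Protocol, SimConfig, run_simulation
from mitoca.geometry import build_lattice


@pytest.fixture()
def params() -> CellParams:
    return CellParams()


@pytest.fixture()
def small_grid():
    return build_lattice((4, 2, 2), (4, 1, 1))


@pytest.fixture(scope="session")
def depolarized_run_30s():
    """30-s free-running paced simulation of the reduced lattice under the
    depolarized condition (alpha_mPTP = 60, PCL 500 ms, seed 1)."""
    traj, snap = run_simulation(
        SimConfig(duration=30000.0, seed=1),
        Protocol(pcl=500.0, alpha_mptp=60.0),
        preset="reduced",
    )
    return traj, snap


@pytest.fixture(scope="session")
def control_run_15s():
    """15-s control run (alpha_mPTP = 1) at PCL 500 ms on the reduced lattice."""
    traj, _ = run_simulation(
        SimConfig(duration=15000.0, seed=1),
        Protocol(pcl=500.0, alpha_mptp=1.0),
        preset="reduced",
    )
    return traj
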