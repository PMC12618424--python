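import numpy as np
import pytest

import cardioloop as cl


@pytest.fixture(scope="session")
def tof_scenario():
    return cl.make_tof_scenario(seed=0)


@pytest.fixture(scope="session")
def periodic_run(tof_scenario):
    """Deeply converged periodic trajectory of the default regurgitant scenario."""
    traj, report = cl.run_to_periodic(tof_scenario, eps_cycl=5e-4, max_cycles=60)
    assert report.converged
    return traj, report


@pytest.fixture(scope="session")
def noiseless_mset(tof_scenario, periodic_run):
    traj, _ = periodic_run
    return cl.synthesize_measurements(traj, tof_scenario.T_cycl, noise=None, seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def twin_report():
    """One shared noiseless end-to-end twin experiment."""
    return cl.run_twin_experiment(seed=0, noise="none")
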