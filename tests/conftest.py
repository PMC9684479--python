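import numpy as np
import pytest

import spanreg as sr


@pytest.fixture(scope="session")
def sim_grid():
    """The standard simulation T2 grid: 200 points, 1 ms spacing on [1, 200]."""
    return sr.make_t2_grid(200, 1.0, 200.0)


@pytest.fixture(scope="session")
def sim_times():
    """150 evenly spaced measurement times in [0.3, 400] ms."""
    return sr.make_time_grid(150, 0.3, 400.0)


@pytest.fixture(scope="session")
def sim_kernel(sim_times, sim_grid):
    return sr.build_kernel(sim_times, sim_grid)


@pytest.fixture(scope="session")
def toy_grid():
    """Well-conditioned small T2 grid for exact-recovery checks."""
    return sr.make_t2_grid(50, 5.0, 120.0)


@pytest.fixture(scope="session")
def toy_times():
    return sr.make_time_grid(80, 0.0, 500.0)


@pytest.fixture(scope="session")
def toy_kernel(toy_times, toy_grid):
    return sr.build_kernel(toy_times, toy_grid)


@pytest.fixture(scope="session")
def toy_dictionary(toy_grid):
    return sr.build_dictionary(
        toy_grid, [sr.GaussianFamilySpec(6, 10.0), sr.GaussianFamilySpec(4, 14.0)]
    )


@pytest.fixture(scope="session")
def study_basis(sim_kernel, sim_grid):
    """Offline basis at the simulation-study conditions (SNR 500): the full
    220-member dictionary, 16 log-spaced lambdas in [1e-6, 10], with the
    Monte-Carlo ensemble scaled to n_run=10 to keep the suite fast."""
    G = sr.default_dictionary(sim_grid)
    ladder = sr.LambdaLadder.log_spaced()
    return sr.build_offline_basis(
        sim_kernel, G, ladder, sigma=1.0 / 500.0, n_run=10, seed=1
    )
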