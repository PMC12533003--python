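import numpy as np
import pytest

from multipcr import efficiency, pool, twin


@pytest.fixture(scope="session")
def small_pool():
    return pool.generate_pool(50, "GCall", seed=11)


@pytest.fixture(scope="session")
def noiseless_series():
    """Exact model trajectories with known parameters (the estimator oracle)."""
    rng = np.random.default_rng(7)
    n = 80
    x0 = rng.lognormal(0.0, 0.3, n)
    eps = np.exp(rng.normal(0.0, 0.02, n))
    cycles = [15, 30, 45, 60, 75, 90]
    cov = twin.noiseless_trajectory(x0, eps, cycles)
    series = efficiency.CoverageSeries(
        ids=[f"s{i:03d}" for i in range(n)], cycles=cycles, coverage=cov
    )
    return series, x0, eps


@pytest.fixture(scope="session")
def twin_run():
    params = twin.TwinParameters(seed=5)
    return twin.simulate_serial_protocol(1000, params), params
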