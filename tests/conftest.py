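import numpy as np
import pytest

from ugadecode import KineticParameters, default_m_grid, simulate_multi_condition


@pytest.fixture(scope="session")
def demo_params() -> KineticParameters:
    """The demonstration parameter set used for the variant comparison:
    {k1, k3, kF, T_total, rho, rho_p} = {3, 10, 0.1, 500, 10, 100}."""
    return KineticParameters(k1=3.0, kF=0.1, k3=10.0, T_total=500.0, rho=10.0, rho_p=100.0)


@pytest.fixture(scope="session")
def noiseless_dataset(demo_params):
    """Five-condition noiseless GPS dataset from the demonstration set."""
    return simulate_multi_condition(demo_params, default_m_grid(200), noise_sd=0.0, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_valid_params(rng, n):
    """Random parameter tuples spanning the physiological box."""
    out = []
    for _ in range(n):
        out.append(
            KineticParameters(
                k1=10.0 ** rng.uniform(-2, 2),
                kF=10.0 ** rng.uniform(-2, 4),
                k3=10.0 ** rng.uniform(-2, 2),
                T_total=10.0 ** rng.uniform(1, 3),
                rho=10.0 ** rng.uniform(-2, 4),
                rho_p=10.0 ** rng.uniform(-1, 3),
            )
        )
    return out
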