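import numpy as np
import pytest

from icolike import BackendConfig, Dataset
from icolike.simulate import SimulationSpec, generate_sine_base, inject_outlier


@pytest.fixture(scope="session")
def ols_config():
    return BackendConfig(backend="ols", seed=0)


@pytest.fixture(scope="session")
def gpr_config():
    # 3 optimizer starts: enough for the smooth noiseless benchmarks
    return BackendConfig(backend="gpr", n_restarts=3, seed=0)


@pytest.fixture(scope="session")
def sine_base():
    return generate_sine_base()


@pytest.fixture(scope="session")
def dataset_ico(sine_base):
    """Sine base plus an interior off-curve point: an ICO by construction."""
    spec = SimulationSpec().with_outlier("inconsistent", x=3.0, delta_y=1.5)
    return inject_outlier(sine_base, spec)


@pytest.fixture(scope="session")
def dataset_co(sine_base):
    """Sine base plus an on-curve extrapolated point: a CO by construction."""
    spec = SimulationSpec().with_outlier("consistent", x=9.0)
    return inject_outlier(sine_base, spec)


@pytest.fixture
def linear_dataset():
    """Noiseless y = 2x on x = 0..9."""
    x = np.arange(10, dtype=float)
    return Dataset(ids=tuple(str(i + 1) for i in range(10)),
                   X=x.reshape(-1, 1), y=2.0 * x)


def random_dataset(rng, n=None, p=None):
    """Small random full-rank regression problem with unique ids."""
    n = n or int(rng.integers(5, 13))
    p = p or int(rng.integers(1, 3))
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + rng.normal(scale=0.3, size=n)
    ids = tuple(f"s{i}" for i in range(n))
    return Dataset(ids=ids, X=X, y=y)
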