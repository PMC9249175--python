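import numpy as np
import pytest

from scratchabc import CellPopulation, Domain, ModelParams


@pytest.fixture
def domain():
    return Domain()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def wounded_population(domain, rng):
    """~320-cell monolayer with a ~520-um central wound band."""
    n = 320
    x = rng.uniform(0, domain.width_x, n)
    lower = rng.random(n) < 0.5
    y = np.where(lower,
                 rng.uniform(0, 500.0, n),
                 rng.uniform(1020.0, domain.width_y, n))
    return CellPopulation(np.column_stack([x, y]), time=0.0, domain=domain)


@pytest.fixture
def neutral_params():
    """Density-independent parameters (pure random walk + birth-death)."""
    return ModelParams(m=1.0, p=0.02, d=0.01, gamma_m=0.0, gamma_p=0.0,
                       gamma_b=0.0)
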