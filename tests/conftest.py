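import numpy as np
import pytest

import sddestab as sd


@pytest.fixture(scope="session")
def fixed_delay_cfg():
    """Unregulated self-renewal, regulated division, constant g with tau = 1.5."""
    return sd.scenario("(s)_d,(pv)_0", mu=1.0, p=2.0, tau=1.5)


@pytest.fixture(scope="session")
def fixed_delay_eq(fixed_delay_cfg):
    return sd.positive_equilibrium(fixed_delay_cfg)


@pytest.fixture(scope="session")
def pv1_cfg():
    """Maturation rate decreasing in the mature-cell amount (k1 = 1)."""
    return sd.scenario("(s)_d,(pv)_1", mu=1.0, p=2.0)


@pytest.fixture(scope="session")
def px_cfg():
    """Maturity- and v-dependent maturation rate (kernel-active scenario)."""
    return sd.scenario("(s)_d,(pv)_2,(px)_2,linear", mu=0.8, p=2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
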