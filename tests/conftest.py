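import numpy as np
import pytest

import mgrdme as mg


@pytest.fixture(scope="session")
def eq_first_order():
    """Fast-slow conversion benchmark: k1=100, k2=2, k3=1 on L=2, K=40."""
    return mg.make_model(mg.fixture("first_order_fig1"))


@pytest.fixture(scope="session")
def eq_dimerization():
    """Doi-bridged dimerization benchmark: k1=50, lambda=5, rho=0.02, L=1."""
    return mg.make_model(mg.fixture("dimerization_fig6"))


@pytest.fixture(scope="session")
def toy_first_order():
    """Well-mixed (K=1) toy with small means for generator-oracle checks."""
    return mg.make_model(
        dict(network="first_order", L=1.0, K_A=1, K_B=1,
             D_A=0.16, D_B=0.01, k1=5.0, k2=2.0, k3=1.0)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
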