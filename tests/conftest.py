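import numpy as np
import pytest

from instpgg import ModelParams


@pytest.fixture
def params():
    """Standard well-mixed parameter set (g=5, r=1.7, cg=0.398, pi0=2, nu=1e-3)."""
    return ModelParams()


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def random_simplex_points(rng, n):
    """n interior points of the 4-simplex (Dirichlet(1,1,1,1))."""
    return rng.dirichlet(np.ones(4), size=n)
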