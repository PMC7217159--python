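import numpy as np
import pytest

from opencohort import (BlockExchangeableComponents, PowerQuery, stepped_wedge)


@pytest.fixture
def school_design():
    """Three-sequence stepped wedge, 4 clusters per sequence, 10 students per
    school-period (the self-esteem trial configuration)."""
    return stepped_wedge(3, (4, 4, 4), 10)


@pytest.fixture
def school_components():
    return BlockExchangeableComponents(sigma2=25, rho=0.33, pi=0.9, tau=0.7)


@pytest.fixture
def school_query():
    return PowerQuery(theta=2.0, alpha=0.05, target_power=0.893)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
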