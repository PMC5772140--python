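import numpy as np
import pytest

from netsir import (DiseaseModel, GeneratingFunctionSet, StaticNetwork,
                    make_degree_distribution, parse_delay_spec)


@pytest.fixture(scope="session")
def g_regular5():
    return GeneratingFunctionSet(make_degree_distribution("regular", k=5))


@pytest.fixture(scope="session")
def g_regular3():
    return GeneratingFunctionSet(make_degree_distribution("regular", k=3))


@pytest.fixture(scope="session")
def g_powerlaw():
    return GeneratingFunctionSet(
        make_degree_distribution("powerlaw_truncated", exponent=2.5, kmin=3, kmax=60))


@pytest.fixture(scope="session")
def markovian_model():
    """Poisson transmission 0.3, exponential recovery 0.5 (mean period 2)."""
    return DiseaseModel(parse_delay_spec("exp:0.3"), parse_delay_spec("exp:0.5"))


@pytest.fixture(scope="session")
def fixed_recovery_model():
    """Poisson transmission 0.3, fixed infectious period 2."""
    return DiseaseModel(parse_delay_spec("exp:0.3"), parse_delay_spec("fixed:2"))


@pytest.fixture(scope="session")
def normal_recovery_model():
    """Poisson transmission 0.3, truncated-normal(2, 0.75) infectious period."""
    return DiseaseModel(parse_delay_spec("exp:0.3"), parse_delay_spec("normal:2,0.75"))


@pytest.fixture(scope="session")
def star5():
    return StaticNetwork(5, [(0, 1), (0, 2), (0, 3), (0, 4)])


@pytest.fixture(scope="session")
def path2():
    return StaticNetwork(2, [(0, 1)])


def sup_gap(a, b):
    """Largest sup-norm gap across the S, I, R series of two trajectories."""
    return max(float(np.max(np.abs(getattr(a, k) - getattr(b, k))))
               for k in ("S", "I", "R"))
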