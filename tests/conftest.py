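import numpy as np
import pytest

from pherosim.classify import ClassThresholds
from pherosim.diffusion import Geometry, default_transport_params
from pherosim.response import DoseResponseParams, ReporterParams


@pytest.fixture(scope="session")
def geom():
    return Geometry(source_extent_h=5.0, domain_length_l=10.0)


@pytest.fixture(scope="session")
def transport():
    return default_transport_params(c0_initial=10.0)


@pytest.fixture(scope="session")
def dose():
    return DoseResponseParams()


@pytest.fixture(scope="session")
def reporter():
    return ReporterParams()


@pytest.fixture(scope="session")
def thresholds():
    return ClassThresholds()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
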