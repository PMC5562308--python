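import numpy as np
import pytest

from cuaging import ModelParams, SoilSample, field_soils_fixture


@pytest.fixture
def published_params():
    """The published long-term fit: B=1.14, C=0, N=214.91, F=2.85, G=0."""
    return ModelParams()


@pytest.fixture
def hygum1():
    """First field soil: pH 5.43, 288.0 K, 78 y of aging, 2.58 % SOC."""
    return SoilSample.from_years("Hygum1", ph=5.43, corg=2.58, temperature=288.0, years=78)


@pytest.fixture(scope="session")
def field_soils():
    return field_soils_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
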