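import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from imk import FieldConfig, nte_params, te_params

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ago_uniform_te():
    return te_params("AGO1522", "uniform")


@pytest.fixture(scope="session")
def ago_half_te():
    return te_params("AGO1522", "half_field")


@pytest.fixture(scope="session")
def du145_half_te():
    return te_params("DU145", "half_field")


@pytest.fixture(scope="session")
def ago_nte():
    return nte_params("AGO1522")


@pytest.fixture(scope="session")
def du145_nte():
    return nte_params("DU145")


@pytest.fixture(scope="session")
def half_field():
    return FieldConfig(a_if=0.5)


@pytest.fixture(scope="session")
def uniform_field():
    return FieldConfig(a_if=1.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
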