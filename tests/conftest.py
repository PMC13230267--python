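import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from netswitch.synthetic import make_region_table

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def region_table_40():
    return make_region_table(40, 8)


@pytest.fixture(scope="session")
def base_allegiance_40(region_table_40):
    return dict(zip(region_table_40["region_id"],
                    region_table_40["rsn_label"].astype(int)))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
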