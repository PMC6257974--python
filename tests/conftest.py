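import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lungpcm as lp

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def france_params():
    return lp.default_params("France")


@pytest.fixture(scope="session")
def all_params():
    return {c: lp.default_params(c) for c in ("France", "Germany", "Italy", "Spain")}


def make_series(apc=5.0, base=100.0, years=(2000, 2011), noise_cv=0.0, seed=0,
                country="France", sex="M", cohort="55-59"):
    spec = lp.TrendSpec(country, sex, cohort, base, ((years[0], apc),), noise_cv, years)
    return lp.generate_registry_series(spec, seed)


@pytest.fixture
def noise_free_series():
    return make_series()
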