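import numpy as np
import pytest

from cellclock.model import ModelParams
from cellclock.synth import make_fixture


@pytest.fixture(scope="session")
def free37():
    params, spec = make_fixture("REF-FREE37")
    return params, spec


@pytest.fixture(scope="session")
def a37():
    params, spec = make_fixture("REF-A37")
    return params, spec


@pytest.fixture(scope="session")
def uncoupled_24_18():
    return ModelParams(T1=24.0, T2=18.0, sigma1=0.15, sigma2=0.2)


@pytest.fixture(scope="session")
def free37_cohort(free37):
    """Moderate division-free cohort reused by several statistical tests."""
    from cellclock.simulate import simulate_cohort

    params, _ = free37
    return simulate_cohort(params, 400, duration=72.0, seed=101, burn_in=0.0)
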