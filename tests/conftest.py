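import numpy as np
import pytest

from ofhl import Params, fit, load_fixture


@pytest.fixture(scope="session")
def covid():
    return load_fixture("covid_mexico")


@pytest.fixture(scope="session")
def survival():
    return load_fixture("chemo_survival")


@pytest.fixture(scope="session")
def covid_mle(covid):
    return fit(covid, "mle")


@pytest.fixture(scope="session")
def survival_mle(survival):
    return fit(survival, "mle")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(
    params=[(0.25, 0.75), (1.5, 0.5), (1.25, 1.25), (1.0, 1.0)],
    ids=lambda v: f"a{v[0]}-t{v[1]}",
)
def params_grid(request):
    return Params(*request.param)
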