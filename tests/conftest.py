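import pytest

from oasim import build_default_parameters, initialize_population


@pytest.fixture(scope="session")
def params():
    return build_default_parameters(1)


@pytest.fixture(scope="session")
def small_pop(params):
    return initialize_population(params, 2000, 2020, seed=7)
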