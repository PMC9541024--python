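import numpy as np
import pytest

from piglet_pkpd.config import design_from_config, load_config, load_population

MODEL_NAMES = ("ketoprofen_pge2", "ketoprofen_cortisol", "flunixin_cortisol")


@pytest.fixture(scope="session", params=MODEL_NAMES)
def model_name(request):
    return request.param


@pytest.fixture(scope="session")
def populations():
    return {name: load_population(name) for name in MODEL_NAMES}


@pytest.fixture(scope="session")
def designs():
    return {name: design_from_config(load_config(name)) for name in MODEL_NAMES}


@pytest.fixture(scope="session")
def keto_pge2(populations):
    return populations["ketoprofen_pge2"]


@pytest.fixture(scope="session")
def keto_cortisol(populations):
    return populations["ketoprofen_cortisol"]


@pytest.fixture(scope="session")
def flunixin(populations):
    return populations["flunixin_cortisol"]


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
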