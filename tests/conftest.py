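import numpy as np
import pytest

from reflexwalk import load_config


@pytest.fixture(scope="session")
def config():
    return load_config()


@pytest.fixture(scope="session")
def synthetic_pair():
    from reflexwalk import SyntheticSpec, make_trial
    return make_trial(SyntheticSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
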