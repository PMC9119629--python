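import numpy as np
import pytest

from presyn.params import builtin_bundle


@pytest.fixture(scope="session")
def bundle():
    return builtin_bundle()


@pytest.fixture(scope="session")
def syt1(bundle):
    """Synchronous sensor: 5 calcium binding sites, fast kinetics."""
    return bundle.sensors["synchronous"]


@pytest.fixture(scope="session")
def syt7(bundle):
    """Asynchronous sensor: 2 calcium binding sites, slow kinetics."""
    return bundle.sensors["asynchronous"]


@pytest.fixture(scope="session")
def sync_model(bundle):
    """Four-component synchronous release profile (400 nm from the cluster)."""
    return bundle.release_models["synchronous"]


@pytest.fixture(scope="session")
def async_model(bundle):
    return bundle.release_models["asynchronous"]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
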