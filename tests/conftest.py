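import numpy as np
import pytest

from spinsys.chem import FeatureConfig
from spinsys.fixtures import FixtureSpec, generate_fixtures


@pytest.fixture(scope="session")
def small_fixture_set():
    """A small deterministic labeled dataset shared across tests."""
    spec = FixtureSpec(n_molecules=24, seed=101, n_conformers=4)
    return generate_fixtures(spec)


@pytest.fixture(scope="session")
def fast_feature_config():
    return FeatureConfig(n_conformers=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
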