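import numpy as np
import pytest

from ebvs import enumerate_models, sachs_like_fixture


@pytest.fixture(scope="session")
def fixture_world():
    """The default 11-protein, 4-pathway world (scenario 1, full sample)."""
    return sachs_like_fixture(1, scenario=1)


@pytest.fixture(scope="session")
def small_space():
    return enumerate_models(3, 3)


@pytest.fixture()
def toy_instance():
    """Tiny (n=6, p=2) regression instance for oracle comparisons."""
    rng = np.random.default_rng(1)
    X = rng.standard_normal((6, 2))
    Y = X[:, 0] + 0.5 * X[:, 0] * X[:, 1] + 0.3 * rng.standard_normal(6)
    return X, Y
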