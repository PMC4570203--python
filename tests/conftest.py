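import numpy as np
import pytest

from famcross.synth import FixtureSpec, generate


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic universe shared by the read-only tests."""
    return generate(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def manifest(bundle):
    return bundle.manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
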