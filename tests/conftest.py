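import numpy as np
import pytest
from hypothesis import settings

from adnaplace import FixtureSpec, make_fixture

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A 32-taxon synthetic tree + alignment shared across tests."""
    return make_fixture(FixtureSpec(n_taxa=32, alignment_length=1500,
                                    gc_content=0.4, substitution_scale=1.0,
                                    seed=0))
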