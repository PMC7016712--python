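import numpy as np
import pytest
from hypothesis import settings

from mthet import build_synthetic_genome, default_genome_spec

settings.register_profile("ci", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def genome():
    """The default ~14.4 kb synthetic mtgenome (AF16-like architecture)."""
    return build_synthetic_genome(default_genome_spec(), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
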