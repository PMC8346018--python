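import numpy as np
import pytest

from screenlib.fitness import FitnessContext
from screenlib.synth import FixtureConfig, synth_annotation_pool


@pytest.fixture(scope="session")
def small_fixture():
    """A small annotation-tier pool shared across GA/fitness tests."""
    return synth_annotation_pool(
        FixtureConfig(n_compounds=60, n_targets=25, n_families=10, seed=11)
    )


@pytest.fixture(scope="session")
def small_context(small_fixture):
    fix = small_fixture
    return FitnessContext(fix.pool_ids, fix.predictions, fix.assignment, fix.novelty)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
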