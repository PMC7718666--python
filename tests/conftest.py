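import numpy as np
import pytest

from octaquant import synthetic


@pytest.fixture(scope="session")
def default_scene():
    """One default SCP scene with ground truth (seeded, shared across tests)."""
    return synthetic.generate_vessel_network(synthetic.AngioSceneParams(seed=1))


@pytest.fixture(scope="session")
def scene_pair():
    """One eye's SCP + DCP scene pair."""
    return synthetic.generate_scene_pair(seed=5)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-size cohort (24/37/29) with its generating truth."""
    return synthetic.generate_cohort(synthetic.CohortParams(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
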