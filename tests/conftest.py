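import numpy as np
import pytest

from strma.simulate import make_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def experiment():
    """One full simulated MA design shared by landscape/rate tests."""
    return make_experiment(seed=11)


@pytest.fixture(scope="session")
def genotype_map(experiment):
    return {m.line_id: m.genotype for m in experiment.meta}
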