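import numpy as np
import pytest

from gonogonet import EquivalenceExperiment, TrainingConfig


@pytest.fixture(scope="session")
def exp1_model():
    return EquivalenceExperiment.experiment1()


@pytest.fixture(scope="session")
def exp2_model():
    return EquivalenceExperiment.experiment2()


@pytest.fixture(scope="session")
def exp1_results(exp1_model):
    """Six simulated participants of the auxiliary-class condition."""
    return exp1_model.fit(n_runs=6, base_seed=1)


@pytest.fixture(scope="session")
def exp2_results(exp2_model):
    """Six simulated participants of the condition without auxiliary training."""
    return exp2_model.fit(n_runs=6, base_seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def quick_config():
    """A configuration that trains fast on toy problems."""
    return TrainingConfig(max_epochs=5000)
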