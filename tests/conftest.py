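import pytest

from vqshunt import scenarios
from vqshunt.config import MLPConfig, RunConfig


@pytest.fixture(scope="session")
def small_ds():
    """A small but fully realistic scenario dataset shared across tests."""
    return scenarios.generate(RunConfig(seed=123), n_scenarios=600, n_test=100)


@pytest.fixture(scope="session")
def small_mlp_cfg():
    """A light MLP architecture for fast training in unit tests."""
    return MLPConfig(hidden_layers=2, units_per_layer=32, epochs=600,
                     batch_size=64, learning_rate=3e-3, seed=5)
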