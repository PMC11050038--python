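import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")

import cpbpe as cb


@pytest.fixture
def tiny_dataset() -> cb.Dataset:
    """Three compounds, two descriptors, hand-written values."""
    return cb.Dataset(
        ids=["a", "b", "c"],
        X=np.array([[0.0, 1.0], [2.0, 3.0], [4.0, 5.0]]),
        T=np.array([-6.0, -4.0, -2.0]),
        descriptor_names=["mw", "logp"])


@pytest.fixture(scope="session")
def smooth_dataset() -> cb.Dataset:
    """Smooth quadratic response of 3 informative descriptors out of 6."""
    return cb.generate(cb.SyntheticSpec(m=120, n=6, n_informative=3,
                                        function="quadratic", noise_sd=0.1,
                                        seed=11))


@pytest.fixture(scope="session")
def trained_model(smooth_dataset) -> cb.CPBPEModel:
    """A small combined model shared by read-only tests."""
    return cb.train_cpbpe(smooth_dataset,
                          cb.CPANNConfig(6, 6, epochs=80, seed=11),
                          cb.BPEConfig(hidden_neurons=5, epochs=1000, seed=11))


@pytest.fixture
def neuron_toy() -> cb.NeuronDataset:
    """A hand-sized neuron set for Stage II unit tests."""
    rng = np.random.default_rng(3)
    inputs = rng.uniform(0, 1, (12, 4))
    targets = 0.1 + 0.8 * rng.uniform(0, 1, 12)
    return cb.NeuronDataset(inputs=inputs, targets=targets,
                            neuron_coords=[(i // 4, i % 4) for i in range(12)],
                            occupancy=np.ones(12, dtype=int))
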