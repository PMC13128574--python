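import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_mito():
    """A small ellipsoid volume shared by post-processing/metric tests."""
    from anisoseg.synthetic import SynthSpec, generate_mito_like
    spec = SynthSpec(shape=(8, 64, 64), n_instances=3, structure="ellipsoid", seed=7)
    return generate_mito_like(spec)


@pytest.fixture(scope="session")
def small_neuron():
    from anisoseg.synthetic import SynthSpec, generate_neuron_like
    spec = SynthSpec(shape=(8, 64, 64), n_instances=4, structure="tube", seed=3)
    return generate_neuron_like(spec)
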