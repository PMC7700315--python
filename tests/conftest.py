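import numpy as np
import pytest

from mangocolor import ncs, synthetic


@pytest.fixture(scope="session")
def chart():
    return ncs.default_chart()


@pytest.fixture()
def rng():
    return np.random.default_rng(20201121)


@pytest.fixture()
def fruit_factory():
    """Small synthetic fruit scenes with ground truth."""

    def make(mixture, black=0.0, red=0.0, shape=(96, 120), seed=0, **kw):
        spec = synthetic.CompositionSpec.of(mixture, black=black, red=red)
        return synthetic.make_fruit_image(spec, shape=shape, seed=seed, **kw)

    return make
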