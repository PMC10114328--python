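import numpy as np
import pytest

import fundusdr as f


@pytest.fixture(scope="session")
def small_model():
    """A desk-scale revised model shared by structural and viz tests."""
    return f.build_revised_model(
        f.ModelConfig(input_side=64, width_multiplier=0.25, init_seed=0)
    )


@pytest.fixture(scope="session")
def fundus_sample():
    """One clean diseased synthetic fundus image."""
    return f.generate_fundus(f.SyntheticSpec(seed=11), label=1)


@pytest.fixture(scope="session")
def fundus_sample_64(fundus_sample):
    from fundusdr.preprocess import resize

    return resize(fundus_sample.image, 64, 64)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
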