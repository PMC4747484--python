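import numpy as np
import pytest

import calscore as cs


@pytest.fixture(scope="session")
def default_scene():
    return cs.default_scene(seed=0)


@pytest.fixture(scope="session")
def noiseless_table(default_scene):
    """Score table of the nine-deposit phantom with noise and shadowing off."""
    return cs.score_scene(
        default_scene,
        us_noise=cs.USNoise.none(),
        ct_noise=cs.CTNoise.none(),
        ib_noise_sigma_db=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
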