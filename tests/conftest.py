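import dataclasses

import numpy as np
import pytest

from alloptical import GeneratorConfig, make_population_session


@pytest.fixture(scope="session")
def small_config():
    """A fast population config used by tests that only need structure."""
    return dataclasses.replace(
        GeneratorConfig(),
        seed=0,
        n_rois=60,
        n_v_trials=12,
        n_vp_trials=12,
        fov_um=(600.0, 300.0),
    )


@pytest.fixture(scope="session")
def small_session(small_config):
    return make_population_session(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
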