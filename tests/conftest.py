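import numpy as np
import pytest

from sailrl.task import TaskConfig, make_schedule


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def default_config():
    return TaskConfig()


@pytest.fixture
def schedule(rng, default_config):
    return make_schedule(default_config, rng)


@pytest.fixture
def small_config():
    # 20 pairs in two equal blocks joined by a congruent change
    return TaskConfig(
        n_pairs=20,
        n_blocks=2,
        block_len_range=(10, 10),
        n_congruent_changes=1,
        n_incongruent_cross=0,
        n_incongruent_within=0,
    )
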