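import numpy as np
import pytest

from ncontext import SimulationConfig, simulate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160168)


@pytest.fixture(scope="session")
def small_cfg():
    """Compact but complete study: all relation classes present."""
    return SimulationConfig(
        n_coding=20,
        n_lincrna=3,
        n_antisense=3,
        n_pseudogene=4,
        pseudogene_indel_rate=0.0,
        noise_sd_log2=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_fixture(small_cfg):
    """Annotation, truth, sequences and expression for the small config."""
    return simulate(small_cfg)
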