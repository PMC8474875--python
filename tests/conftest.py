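import numpy as np
import pytest

from isomir_prognosis import simulate


@pytest.fixture(scope="session")
def small_config() -> simulate.SimConfig:
    return simulate.SimConfig(
        n_tumor=40, n_normal=10, n_hairpins=8, seed=7,
        zero_rate=0.05, block_sigma=0.4,
    )


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return simulate.generate_annotation(small_config)


@pytest.fixture(scope="session")
def small_sim(small_config, small_annotation):
    return simulate.generate_isoform_files(small_config, small_annotation)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
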