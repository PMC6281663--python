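import numpy as np
import pytest

from taskphase import synthetic as syn
from taskphase import preprocessing as prep


@pytest.fixture(scope="session")
def templates():
    return syn.make_template_library()


@pytest.fixture(scope="session")
def small_population():
    """A small three-template population with selective and junk units."""
    cfg = syn.SyntheticConfig(
        phase_tuned_per_template=8, n_stimulus_selective=4, n_junk=2,
        trials_per_condition=10, template_ids=(0, 2, 4), seed=42,
    )
    spikes, truth = syn.sample_population(cfg)
    return cfg, spikes, truth


@pytest.fixture(scope="session")
def small_preprocessed(small_population):
    _, spikes, _ = small_population
    return prep.preprocess(spikes)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
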