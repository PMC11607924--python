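import numpy as np
import pytest

import mixcal


@pytest.fixture(scope="session")
def table1():
    return mixcal.load_table1_fixture()


@pytest.fixture(scope="session")
def noiseless_dataset(table1):
    """Zero-distortion spectra for every design row (pure Beer-Lambert)."""
    return mixcal.simulate_dataset(table1)


@pytest.fixture(scope="session")
def mild_noise_dataset(table1):
    cfg = mixcal.DistortionConfig(noise_sd=0.002, seed=11)
    return mixcal.simulate_dataset(table1, cfg=cfg)


@pytest.fixture(scope="session")
def set_ids(table1):
    sets = table1.sets
    return {
        label: list(sets.index[sets == label]) for label in ("M", "St", "T")
    }


@pytest.fixture
def rng():
    return np.random.default_rng(42)
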