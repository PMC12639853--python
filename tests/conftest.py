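import logging

import numpy as np
import pytest

from vocalsmile import simulate
from vocalsmile.stimgen import EqualizerParams

logging.getLogger("vocalsmile").setLevel(logging.WARNING)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def eq_params():
    return EqualizerParams()


@pytest.fixture(scope="session")
def small_cohort():
    """Schema-complete 3+3 cohort with all modalities, shared across tests."""
    return simulate.simulate_cohort(seed=11, n_nt=3, n_asd=3,
                                    n_revcorr_trials=120)
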