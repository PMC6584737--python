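import numpy as np
import pytest

import vwmtradeoff as v
from vwmtradeoff.mixture import FitConfig
from vwmtradeoff.simulate import nontarget_offsets, signed_errors


@pytest.fixture(scope="session")
def recall_block_200():
    """200 recall trials from truth (P, SD) = (0.6, 20 deg), no swaps."""
    trials = v.simulate_recall(0.6, 20.0, 0.0, 200, "low_precision", seed=12345)
    return trials


@pytest.fixture(scope="session")
def errors_200(recall_block_200):
    return signed_errors(recall_block_200)


@pytest.fixture(scope="session")
def swap_block_200():
    """200 recall trials with a 20% swap component."""
    trials = v.simulate_recall(0.55, 20.0, 0.2, 200, "low_precision", seed=777)
    return signed_errors(trials), nontarget_offsets(trials)


@pytest.fixture(scope="session")
def quick_fit_config():
    return FitConfig(n_starts=4, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
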