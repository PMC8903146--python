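import numpy as np
import pytest

import robustpriors as rp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_raw():
    """A small compensatory task, fixed seed."""
    return rp.generate_synthetic_task(m=4, N=20, validity_profile="compensatory",
                                      noise_sd=0.5, seed=7)


@pytest.fixture
def paired_data(small_raw):
    coded = rp.median_split(small_raw, "binary")
    return rp.make_paired_comparisons(coded, small_raw.criterion, seed=7)


@pytest.fixture
def train_test(paired_data):
    return rp.split_train_test(paired_data, rp.SplitSpec(n_train=50, seed=7))
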