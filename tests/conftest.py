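import numpy as np
import pytest

from metamiss.synthetic import (
    generate_correlation_dataset,
    generate_mean_difference_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20201007)


@pytest.fixture
def md_dataset():
    """Standard 100-row mean-difference data set at a fixed seed."""
    return generate_mean_difference_dataset(100, np.random.default_rng(1))


@pytest.fixture
def corr_dataset():
    """Standard 100-row correlation data set at a fixed seed."""
    return generate_correlation_dataset(100, np.random.default_rng(2))
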