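import numpy as np
import pytest

from condel.core import LibraryStats


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def lib():
    return LibraryStats(min_len=100, max_len=200)
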