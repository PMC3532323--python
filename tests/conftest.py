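import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_xy(rng):
    """Well-conditioned random pair of views with aligned compound ids."""
    ids = [f"c{i:03d}" for i in range(50)]
    x = pd.DataFrame(rng.standard_normal((50, 8)), index=ids,
                     columns=[f"d{j}" for j in range(8)])
    y = pd.DataFrame(rng.standard_normal((50, 6)), index=ids,
                     columns=[f"s{j}" for j in range(6)])
    return x, y
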