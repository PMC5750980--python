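import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable


def make_temp(values, start="2000-01-01"):
    """Daily temperature series from a list of values."""
    values = np.asarray(values, dtype=float)
    idx = pd.date_range(start, periods=len(values), freq="D")
    return pd.Series(values, index=idx, name="tmean_c")


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def temp_factory():
    return make_temp
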