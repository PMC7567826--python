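import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from cpelhap import CpelModel
from cpelhap.testing import null_region_layout


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_model(rng, n_sites=None, n_subregions=None, scale=3.0):
    """A random Ising methylation model on a synthetic layout."""
    n = n_sites or int(rng.integers(1, 9))
    k = n_subregions or int(rng.integers(1, min(n, 3) + 1))
    layout = null_region_layout(n, k)
    alpha = tuple(rng.uniform(-scale, scale, size=k))
    beta = float(rng.uniform(-2.0, 2.0))
    return CpelModel(layout, alpha, beta)


@pytest.fixture
def make_random_model(rng):
    return lambda **kw: random_model(rng, **kw)
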