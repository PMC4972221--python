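import numpy as np
import pandas as pd
import pytest

from streamimpact import synthgen


@pytest.fixture(scope="session")
def default_params():
    return synthgen.GeneratorParams(seed=1)


@pytest.fixture(scope="session")
def synthetic_dataset(default_params):
    """One default synthetic study: (abundance, traits, sites, ground truth)."""
    return synthgen.simulate(default_params)


@pytest.fixture
def small_traits():
    """Hand-written 4-taxon trait table for descriptor arithmetic."""
    return pd.DataFrame(
        {
            "saprobic_value": [1.8, 2.8, 3.5, 2.0],
            "saprobic_weight": [4, 2, 4, 3],
            "spear": [True, False, False, True],
            "ept": [True, False, False, True],
            "oligochaete": [False, False, True, False],
        },
        index=["mayfly", "snail", "worm", "caddisfly"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
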