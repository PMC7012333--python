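import dataclasses

import numpy as np
import pytest

import twinace as ta


@pytest.fixture(scope="session")
def small_params():
    """Study-condition generator scaled down for fast tests."""
    p = ta.default_params(seed=11)
    return dataclasses.replace(
        p,
        n_pairs={"MZM": 80, "MZF": 80, "DZM": 80, "DZF": 80, "DZOS": 80},
        n_singletons=80,
    )


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return ta.simulate_cohort(small_params, seed=11)


@pytest.fixture(scope="session")
def small_families(small_cohort):
    return ta.pair_assembly(ta.transform_bdi(small_cohort))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
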