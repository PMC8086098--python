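import numpy as np
import pytest

from dmu import ScenarioConfig, TabularDataset, build_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_two_pattern():
    """Six rows: rows 0-2 observe {x1, x2}, rows 3-5 observe {x2, x3}."""
    M = np.nan
    pred = np.array(
        [
            [1.0, 2.0, M],
            [1.5, 2.5, M],
            [0.5, 1.5, M],
            [M, 3.0, 4.0],
            [M, 3.5, 4.5],
            [M, 2.5, 3.5],
        ]
    )
    y = np.array([1.0, 1.2, 0.8, 2.0, 2.2, 1.8])
    return TabularDataset(outcome=y, predictors=pred, column_names=["x1", "x2", "x3"])


@pytest.fixture(scope="session")
def small_scr_pair():
    """A small-but-structured SCR scenario shared by slower tests."""
    cfg = ScenarioConfig(
        p=8, n_train=400, n_complete_extra=30, n_test=200, missing_rate=0.6, seed=77
    )
    return build_scenario(cfg)
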