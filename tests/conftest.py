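import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pandaniche import core

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """Compact scenario: 6 communities in 2 reserves, 20 households each."""
    return core.ScenarioConfig(n_households=120, n_communities=6,
                               n_reserves=2, seed=11)


@pytest.fixture(scope="session")
def small_tables(small_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {
            "households": core.generate_households(small_config),
            "communities": core.generate_communities(small_config),
            "panda_survey": core.generate_panda_survey(small_config),
            "adjacency": core.generate_adjacency(small_config),
        }


@pytest.fixture(scope="session")
def large_households():
    """5,000 households at the survey-calibrated defaults, for moment
    checks."""
    cfg = core.ScenarioConfig(n_households=5000, n_communities=35,
                              n_reserves=9, seed=2024)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return core.generate_households(cfg)


@pytest.fixture()
def toy_adjusted():
    """3 evaluation units x 4 single-index dimensions, strictly positive."""
    rng = np.random.default_rng(7)
    raw = pd.DataFrame(rng.uniform(0.2, 2.0, size=(3, 4)),
                       index=pd.Index(["C1", "C2", "C3"],
                                      name="community_id"),
                       columns=["x1", "x2", "x3", "x4"])
    dims = {"X1": ("x1",), "X2": ("x2",), "X3": ("x3",), "X4": ("x4",)}
    return raw, dims
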