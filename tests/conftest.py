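import warnings

import numpy as np
import pytest

from scoterhab import preset_scenarios, run_pipeline


@pytest.fixture(scope="session")
def paper_pipeline():
    """One generated paper-like study (no fit), shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(preset_scenarios(seed=1)["paper_like"])


@pytest.fixture(scope="session")
def small_design(paper_pipeline):
    """First 500 rows of the paper-like design (counts + matrix)."""
    d = paper_pipeline.design
    return d.y[:500], d.X[:500]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
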