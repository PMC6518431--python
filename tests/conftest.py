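import datetime as dt

import pytest

from trialtrack import SyntheticConfig, generate_registry


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-trial synthetic cohort shared by read-only tests."""
    config = SyntheticConfig(n_trials=400, seed=11)
    records, corpus, truth = generate_registry(config)
    return config, records, corpus, truth


@pytest.fixture
def snapshot():
    return dt.date(2040, 1, 1)
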