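import pytest

from nutlim import synthetic as syn


@pytest.fixture(scope="session")
def small_survey():
    """A 40-experiment survey reused by I/O, pipeline and trend tests."""
    cfg = syn.SyntheticConfig(seed=7, n_experiments=40)
    return syn.simulate_survey(cfg)


@pytest.fixture(scope="session")
def small_survey_config():
    return syn.SyntheticConfig(seed=7, n_experiments=40)
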