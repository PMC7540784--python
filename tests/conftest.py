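import pytest

from tightrope import SimConfig, simulate

GATE_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def default_config():
    return SimConfig()


@pytest.fixture(scope="session")
def table_runs(default_config):
    """Three independent 240 s runs of the default configuration, shared by
    every statistic-level test (the Monte-Carlo replication set)."""
    return [simulate(default_config.with_seed(s)) for s in GATE_SEEDS]
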