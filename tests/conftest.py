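"""Shared fixtures: a small simulated experiment reused across test modules."""

import pytest

from almirna import pipeline
from almirna.simulate import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Reduced-depth configuration for fast end-to-end tests."""
    return pipeline.default_config(seed=7, library_depth=100_000)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    """(truth, refs, reads, expected) for the small simulated experiment."""
    return simulate_experiment(small_config)


@pytest.fixture(scope="session")
def small_run(small_config, tmp_path_factory):
    """Full pipeline result dict on the small experiment."""
    out = tmp_path_factory.mktemp("run")
    return pipeline.run_pipeline(small_config, out)
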