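"""Shared fixtures: one synthetic study, simulated and run once per session."""

import pytest

from mirpipe.pipeline import run_pipeline
from mirpipe.synthetic import (
    SimulationConfig,
    generate_reference_bundle,
    simulate_libraries,
)

STUDY_SEED = 11
STUDY_DEPTH = 20_000


@pytest.fixture(scope="session")
def study_config() -> SimulationConfig:
    return SimulationConfig(seed=STUDY_SEED, library_depth=STUDY_DEPTH)


@pytest.fixture(scope="session")
def study(study_config):
    """(config, bundle, planted truth list, libraries, read-level truth)."""
    bundle, planted = generate_reference_bundle(study_config)
    libraries, truth = simulate_libraries(bundle, planted, study_config)
    return study_config, bundle, planted, libraries, truth


@pytest.fixture(scope="session")
def pipeline_result(study):
    config, bundle, _planted, libraries, _truth = study
    return run_pipeline(libraries, bundle, config.conditions, config.adapter)
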