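import pytest

from panethnet import ScenarioSpec, generate_scenario, write_fixture_set


@pytest.fixture(scope="session")
def default_bundle():
    """Default synthetic world (replicate noise sd = 0.25, seed 7)."""
    return generate_scenario(ScenarioSpec(seed=7))


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Separation-limit world: zero replicate noise, planted truth exact."""
    return generate_scenario(ScenarioSpec(seed=11, noise_sd=0.0))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, default_bundle):
    """Default bundle written to disk; returns (directory, PipelineConfig)."""
    out = tmp_path_factory.mktemp("fixtures")
    config = write_fixture_set(default_bundle, out)
    return out, config


@pytest.fixture(scope="session")
def noiseless_fixture_dir(tmp_path_factory, noiseless_bundle):
    out = tmp_path_factory.mktemp("fixtures_sd0")
    config = write_fixture_set(noiseless_bundle, out)
    return out, config
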