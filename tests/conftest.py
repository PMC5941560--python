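import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default synthetic bundle, shared across
    tests that only inspect its outputs."""
    from tetramerge.pipeline import RunConfig, run_pipeline
    from tetramerge.synth import SimulationConfig

    out = tmp_path_factory.mktemp("default_run")
    config = RunConfig(sim=SimulationConfig(seed=11), out_dir=out)
    return run_pipeline(config)


@pytest.fixture(scope="session")
def noiseless_run(tmp_path_factory):
    """Pipeline run under the noiseless closure configuration: jitter 0,
    no depth noise, no false positives, no QC failures, canonical
    sensitivities of 1."""
    from tetramerge.pipeline import RunConfig, run_pipeline
    from tetramerge.synth import SimulationConfig

    out = tmp_path_factory.mktemp("noiseless_run")
    config = RunConfig(sim=SimulationConfig(seed=7).noiseless(), out_dir=out)
    return run_pipeline(config)
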