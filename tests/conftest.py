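import pytest

from cernet import PipelineConfig, SimulationConfig, generate_dataset, run_pipeline


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic bundle at a fixed seed, shared across tests."""
    return generate_dataset(SimulationConfig(rng_seed=1))


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_mrna=60, n_lncrna=20, n_mirna=15, n_triplets=5, n_reads=100, rng_seed=7
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    cfg = PipelineConfig(out_dir=str(tmp_path_factory.mktemp("pipe")), rng_seed=1)
    return run_pipeline(cfg)
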