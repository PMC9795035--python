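import pytest

from comorbidnet import RunConfig, SimulationConfig, generate_all, run_pipeline_dataset


def small_config(rng_seed: int, **overrides) -> SimulationConfig:
    """Default study conditions on a shorter genome (2 x 500 kb) for
    multi-seed loops; planted structure and thresholds are unchanged."""
    base = dict(
        rng_seed=rng_seed,
        chrom_length_bp=500_000,
        background_contacts=200,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def default_dataset():
    """One dataset at the full default configuration (2 x 2 Mb)."""
    return generate_all(SimulationConfig(rng_seed=42))


@pytest.fixture(scope="session")
def small_dataset():
    return generate_all(small_config(7))


@pytest.fixture(scope="session")
def small_result(small_dataset):
    return run_pipeline_dataset(
        small_dataset, RunConfig(bootstrap_iterations=20, rng_seed=3)
    )
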