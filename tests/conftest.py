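import numpy as np
import pytest

from spadspec import PipelineConfig, SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_data():
    """46-sample dataset on a coarse 2 nm grid; fast stand-in for unit tests."""
    return generate_dataset(
        SynthConfig(n_samples=46, wl_step=2.0, noise_sd=0.002, seed=11)
    )


@pytest.fixture(scope="session")
def noiseless_data():
    return generate_dataset(
        SynthConfig(n_samples=120, wl_step=2.0, noise_sd=0.0, seed=5)
    )


def fast_pipeline_config(master_seed: int = 3) -> PipelineConfig:
    """A complete but small pipeline configuration (coarse 5 nm grid)."""
    return PipelineConfig(
        synth=SynthConfig(n_samples=46, wl_step=5.0, noise_sd=0.002, seed=11),
        master_seed=master_seed,
        spa_size_min=3,
        spa_size_max=8,
        spa_step_nm=5.0,
        alphas=(0.0, 0.4, 1.0),
        edge_trim=5,
        resample_step_nm=5.0,
        pairs_per_map=5,
        single_counts=(2, 3),
        index_counts=(3, 4),
        sma_pop=8,
        sma_iter=10,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
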