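import numpy as np
import pytest

from sclerolink import PipelineConfig, SimConfig, run_pipeline, simulate_study


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down cohort for fast unit tests (full-size conditions are
    exercised in the acceptance suite)."""
    return SimConfig(
        n_transcripts=400,
        n_blister_proteins=160,
        n_plasma_proteins=160,
        n_skin_modules=3,
        n_blister_modules=3,
        n_plasma_modules=1,
        module_size_range=(30, 40),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def small_result(small_study):
    return run_pipeline(small_study, PipelineConfig(seed=11))
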