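import numpy as np
import pytest

from connpredict.synth import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured cohort used across test modules."""
    cfg = SynthConfig(
        n_subjects_A=40, n_subjects_B=12,
        n_nodes=30, n_vertices=600, n_active_vertices=500,
        n_timepoints=60, n_signal_edges=8, seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_cohort():
    """Strong planted signal, no covariate effects, low noise."""
    cfg = SynthConfig(
        n_subjects_A=200, n_subjects_B=15,
        n_nodes=16, n_vertices=300, n_active_vertices=250,
        n_signal_edges=5, intercept=10.0, beta_strength=3.0,
        beta_age=0.0, beta_sex=0.0, beta_baseline=0.0,
        noise_sd=0.5, seed=11,
    )
    return generate_cohort(cfg)
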