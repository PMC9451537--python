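import numpy as np
import pytest

import soundcat as sc


@pytest.fixture(scope="session")
def stimuli():
    return sc.make_stimulus_table()


@pytest.fixture(scope="session")
def small_cohort():
    return sc.generate_cohort({"blind": 4, "sighted": 4}, seed=11)


@pytest.fixture(scope="session")
def signal_betas(stimuli, small_cohort):
    """High-SNR human-geometry β patterns (both ROIs, 60 voxels)."""
    cfg = sc.SimulationConfig(
        n_voxels=60, signal_scale=3.0, noise_sd=0.3, target_model="human", seed=5
    )
    return sc.generate_beta_patterns(small_cohort, stimuli, cfg)


@pytest.fixture(scope="session")
def noise_betas(stimuli, small_cohort):
    """Noise-only β patterns (no category signal anywhere)."""
    cfg = sc.SimulationConfig(n_voxels=60, signal_scale=0.0, noise_sd=1.0, seed=6)
    return sc.generate_beta_patterns(small_cohort, stimuli, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
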