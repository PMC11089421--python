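import numpy as np
import pytest

from dynconn import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small cohort (6 subjects, 2 states) for fast structural tests."""
    cfg = SyntheticConfig(
        n_subjects_per_group=3, n_sources=5, n_voxels=80, n_timepoints=120,
        n_states=2, seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
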