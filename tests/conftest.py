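import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def small_dataset():
    """A small labelled synthetic dataset shared across tests."""
    from apoedit.simulate import SimConfig, synth_dataset

    cfg = SimConfig(
        seed=11,
        n_edited_up_hypoxia=15,
        n_edited_up_normoxia=5,
        n_snp_het=8,
        n_snp_hom=8,
        n_noise=10,
        n_null=20,
        depth_range=(100, 200),
    )
    return synth_dataset(cfg)
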