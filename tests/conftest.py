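import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_bn():
    """Small 3-group Balding-Nichols dataset with a little missingness."""
    from diffscan.synthetic import BNConfig, simulate_genotypes

    cfg = BNConfig(
        n_groups=3, samples_per_group=12, n_sites=400, F=0.05,
        missing_rate=0.05, seed=42,
    )
    gm, _ = simulate_genotypes(cfg)
    return gm


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
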