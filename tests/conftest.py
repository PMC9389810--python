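import pytest

from cusum_gfr.cusum import NormalReference
from cusum_gfr.simulate import SimConfig, simulate_cohort

from helpers import make_series


@pytest.fixture(scope="session")
def small_sim():
    """Seeded synthetic cohort with decoys, shared across tests."""
    cfg = SimConfig(n_normal=150, n_progressor=40, seed=42, decoys=True)
    return cfg, simulate_cohort(cfg)


@pytest.fixture
def flat_reference():
    """Reference with no age decline and a flat per-age mean of 85, SD 5."""
    return NormalReference(
        mu0_by_age={a: 85.0 for a in range(18, 100)},
        sigma=5.0,
        decline_rate=0.0,
        overall_mean=85.0,
    )


@pytest.fixture
def series_factory():
    return make_series
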