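import numpy as np
import pytest

from aircausal.simulate import (
    CoupledMapConfig,
    HealthSimConfig,
    simulate_coupled_maps,
    simulate_counts,
    simulate_exposure,
)


@pytest.fixture(scope="session")
def coupled_series():
    """One-way coupled chaotic maps (Y drives X), length 1000."""
    cfg = CoupledMapConfig(beta_xy=0.32, beta_yx=0.0, n=1200, burn_in=200,
                           seed=11)
    return simulate_coupled_maps(cfg)


@pytest.fixture(scope="session")
def uncoupled_series():
    cfg = CoupledMapConfig(beta_xy=0.0, beta_yx=0.0, n=1200, burn_in=200,
                           seed=12)
    return simulate_coupled_maps(cfg)


@pytest.fixture(scope="session")
def synthetic_study():
    """A 2000-day exposure/count pair with a known lag-0 effect."""
    exposure = simulate_exposure(2005, seed=1)
    cfg = HealthSimConfig(n_days=2000, beta1=(0.0016,), seed=2)
    counts = simulate_counts(exposure, cfg)
    return exposure, counts, cfg
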