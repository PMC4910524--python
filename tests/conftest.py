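import warnings

import pytest

from twinace.synthetic_twins import (
    ACEParams,
    SimulationConfig,
    simulate_teds_like,
    teds_default_config,
)


@pytest.fixture(scope="session")
def teds_cohort():
    """Study-shaped cohort at the headline generating values (fixed seed)."""
    return simulate_teds_like(teds_default_config(seed=20160616))


@pytest.fixture(scope="session")
def balanced_continuous_groups():
    """Large MZ+DZ pair arrays at interior truth (0.6, 0.2, 0.2)."""
    from twinace.synthetic_twins import simulate_pair_arrays

    cfg = SimulationConfig(
        n_mzm=5000, n_mzf=0, n_dzm=5000, n_dzf=0, n_dzos=0,
        ace=ACEParams(0.6, 0.2, 0.2), seed=61,
    )
    arrays = simulate_pair_arrays(cfg)
    return {g.gamma: xy for g, xy in arrays.items()}


@pytest.fixture(autouse=True)
def _quiet_power_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*pairs.*")
        yield
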