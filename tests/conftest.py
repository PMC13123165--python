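import numpy as np
import pandas as pd
import pytest

from equitarget import SimulationConfig, simulate_panel

#: One fixed seed for every fixture that needs reproducible randomness.
SEED = 20260919


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=SEED,
        n_regions=2,
        n_areas_per_region=40,
        households_per_area=(15, 30),
        years=(2018, 2019, 2020, 2021),
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_panel(small_config)


@pytest.fixture(scope="session")
def default_sim():
    """One full default-size register draw, shared by the invariant checks."""
    return simulate_panel(SimulationConfig(seed=SEED))


@pytest.fixture()
def toy_panel():
    """Deterministic 6-row, 3-cluster, 2-year panel for regression oracles."""
    rng = np.random.default_rng(SEED)
    n = 6
    return pd.DataFrame(
        {
            "area_id": ["a", "a", "b", "b", "c", "c"],
            "region": ["R1", "R1", "R1", "R2", "R2", "R2"],
            "year": [2018, 2019, 2018, 2019, 2018, 2019],
            "relative_cni": [0.4, 0.4, 1.1, 1.1, 2.0, 2.0],
            "dosage": rng.random(n) * 0.4,
            "n_households": [30, 30, 55, 55, 80, 80],
        }
    )


def skewed_panel(n=1000, zero_share=0.7, seed=SEED):
    """Zero-heavy allocation: no dosage below a need cutoff, rising above it.

    Mimics a staged programme that has reached only the neediest areas, with
    the zero mass placed where the fitted line is lowest so least-squares
    residual classification stays near half-and-half.
    """
    rng = np.random.default_rng(seed)
    need = rng.uniform(0.0, 2.0, n)
    cutoff = np.quantile(need, zero_share)
    dosage = np.where(
        need >= cutoff,
        0.28 + 0.3 * (need - cutoff) + rng.normal(0, 0.12, n),
        0.0,
    )
    dosage = np.clip(dosage, 0, 1)
    return pd.DataFrame(
        {
            "area_id": [f"a{i}" for i in range(n)],
            "year": 2020,
            "relative_cni": need,
            "dosage": dosage,
            "n_households": 50,
        }
    )


@pytest.fixture()
def skewed_fixture():
    return skewed_panel()
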