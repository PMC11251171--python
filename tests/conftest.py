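import numpy as np
import pandas as pd
import pytest

from mycoforest import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_ecoregions=5, plots_per_ecoregion=12, n_species=60, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """A 60-plot synthetic bundle shared by read-only tests."""
    ds, truth = simulate_dataset(small_config)
    return ds, truth


@pytest.fixture
def toy_species() -> pd.DataFrame:
    """Four species covering every strategy and seral status."""
    traits = {t: [10.0, 20.0, 30.0, 40.0] for t in
              ["Cmass", "Nmass", "Pmass", "Kmass", "LA", "SLA", "LMA", "LDMC"]}
    return pd.DataFrame({
        "species_id": ["A", "B", "C", "D"],
        "strategy": ["EcM", "AM", "dual", "other"],
        "seral_status": ["pioneer", "climax", "neither", "neither"],
        **traits,
    })


def make_stems(rows):
    """rows: (plot_id, subplot, species_id, dbh, height) tuples."""
    return pd.DataFrame(rows, columns=["plot_id", "subplot", "species_id", "dbh", "height"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
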