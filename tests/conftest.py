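import numpy as np
import pytest

from nichecycle.config import SimConfig
from nichecycle.simulate import simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """Small but complete synthetic community: 20 ASVs in 5 genera, 11 y."""
    cfg = SimConfig(n_genera=5, asvs_per_genus=4, reads_per_sample=20_000,
                    n_crt=2, seed=42)
    dataset, truth = simulate_dataset(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def uneven_times():
    """A realistic uneven monthly time axis (days), n = 131."""
    rng = np.random.default_rng(7)
    months = np.arange(131) * 30.4375
    return np.sort(months + rng.uniform(0, 28, size=131))
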