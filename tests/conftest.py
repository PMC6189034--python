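import numpy as np
import pandas as pd
import pytest

from nichediv import synthdata
from nichediv.trees import TimeTree


@pytest.fixture(scope="session")
def yule_tree() -> TimeTree:
    """50-tip pure-birth tree, crown age 100 Myr."""
    return synthdata.simulate_bd_tree(50, birth=0.1, death=0.0, crown_age=100.0, seed=11)


@pytest.fixture(scope="session")
def big_tree() -> TimeTree:
    """200-tip tree for recovery experiments."""
    return synthdata.simulate_bd_tree(200, birth=0.1, death=0.0, crown_age=100.0, seed=13)


@pytest.fixture(scope="session")
def small_grid():
    """12x12 environmental grid with moderate spatial autocorrelation."""
    return synthdata.simulate_environment(12, 12, autocorr_range=3.0, seed=21)


@pytest.fixture(scope="session")
def toy_overlaps():
    """Overlap matrices over 12 synthetic species (random surfaces/points)."""
    from nichediv.clade_metrics import OverlapMatrices

    rng = np.random.default_rng(7)
    species = [f"s{i}" for i in range(12)]
    surfaces = {s: rng.uniform(size=40) for s in species}
    occsets = {
        s: pd.DataFrame({"lon": rng.uniform(0, 20, 6), "lat": rng.uniform(-10, 10, 6)})
        for s in species
    }
    return OverlapMatrices.build(surfaces, occsets)
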