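import numpy as np
import pandas as pd
import pytest

from multinmix import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_community():
    """K=2 community with correlated extra-Poisson noise, observed layer."""
    Sigma = np.array([[0.6, 0.4], [0.4, 0.6]])
    cfg = SimulationConfig(n_locations=40, n_dates=3, K=2, J=4,
                           beta=[[0.8], [0.5]], alpha=[[0.0], [0.3]],
                           Sigma=Sigma, seed=42)
    return simulate(cfg)


@pytest.fixture(scope="session")
def poisson_single():
    """Single pure-Poisson species, 500 surveys: step-1 null conditions."""
    cfg = SimulationConfig(n_locations=250, n_dates=2, K=1, J=4,
                           beta=[[1.0]], alpha=[[0.0]], seed=7)
    return simulate(cfg)


@pytest.fixture()
def intercept_designs():
    def _make(I):
        return np.ones((I, 1)), np.ones((I, 1))

    return _make


@pytest.fixture()
def tiny_files(tmp_path):
    """Hand-written three-file fixture: 2 locations x 3 dates x 2 species."""
    obs = pd.DataFrame([
        # location, date, time, species, h1..h4
        ["A", "1983-06-01", "06:10", "REVI", 1, 0, 1, 0],
        ["A", "1983-06-01", "06:10", "REVI", 1, 1, 0, 0],
        ["A", "1983-06-01", "06:10", "HOWR", 0, 0, 0, 1],
        ["A", "1983-06-15", "07:20", "REVI", 1, 1, 1, 1],
        ["B", "1983-06-01", "08:45", "HOWR", 0, 1, 0, 0],
        ["B", "1983-06-29", "09:00", "REVI", 1, 0, 0, 0],
    ], columns=["location", "date", "time", "species", "h1", "h2", "h3", "h4"])
    hab = pd.DataFrame({"location": ["A", "B"],
                        "patch_area": [12.0, 300.0],
                        "forest_cover": [0.3, 0.9]})
    spt = pd.DataFrame({"species": ["REVI", "HOWR"],
                        "common_name": ["Red-eyed Vireo", "House Wren"]})
    paths = {}
    for name, df in [("observations", obs), ("habitat", hab), ("species", spt)]:
        p = tmp_path / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths
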