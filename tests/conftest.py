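import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from hetfit import heterozygosity, marker_stats
from hetfit.io_core import GenotypeMatrix, MarkerPanel
from hetfit.synthetic_data import SimConfig, simulate_dataset


@pytest.fixture
def small_panel() -> MarkerPanel:
    return MarkerPanel(pd.DataFrame({
        "locus": ["LocA", "LocB", "LocC", "LocD"],
        "chromosome": ["1", "1", "2", "3"],
        "category": ["neutral", "neutral", "functional", "functional"],
    }))


@pytest.fixture
def small_genotypes() -> GenotypeMatrix:
    # LocA: (1/1),(1/2),(2/2),(1/2)  -> A_R=2, H_O=0.5, E=0.5
    # LocB: monomorphic (3/3)
    # LocC: all heterozygous (1/2)
    # LocD: mixed with one missing pair
    a1 = np.array([[1, 3, 1, 5],
                   [1, 3, 1, 5],
                   [2, 3, 1, 0],
                   [1, 3, 1, 6]])
    a2 = np.array([[1, 3, 2, 5],
                   [2, 3, 2, 6],
                   [2, 3, 2, 0],
                   [2, 3, 2, 6]])
    return GenotypeMatrix(np.array(["i1", "i2", "i3", "i4"], dtype=object),
                          ["LocA", "LocB", "LocC", "LocD"], a1, a2)


@pytest.fixture(scope="session")
def sim_study():
    """A small but complete simulated study shared across tests."""
    cfg = SimConfig(seed=20240601, n_per_year=120, n_years=4)
    return cfg, simulate_dataset(cfg)


@pytest.fixture(scope="session")
def sim_het_table(sim_study):
    cfg, study = sim_study
    w = marker_stats.expected_het_weights(marker_stats.marker_summary(study.genotypes))
    subsets = {name: study.panel.subset(name) for name in ("total", "neutral", "functional")}
    return heterozygosity.het_estimates(study.genotypes, w, subsets)
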