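import numpy as np
import pandas as pd
import pytest

from midas_mhc.io import AlleleCatalog, GenotypeTable
from midas_mhc.synthdata import SimulationConfig, simulate_allele_pool, simulate_populations


@pytest.fixture(scope="session")
def small_catalog() -> AlleleCatalog:
    """30 unique stop-free 47-codon alleles from one seeded simulation."""
    cfg = SimulationConfig(n_alleles=30, seed=11)
    return simulate_allele_pool(cfg)


@pytest.fixture(scope="session")
def small_truth(small_catalog):
    cfg = SimulationConfig(n_alleles=30, n_populations=4,
                           n_individuals_per_population=10,
                           pool_size_range=(15, 25), scenario="none", seed=11)
    return simulate_populations(small_catalog, cfg)


@pytest.fixture()
def toy_samples() -> pd.DataFrame:
    return pd.DataFrame({
        "individual_id": ["i1", "i2", "i3"],
        "population": ["p1", "p1", "p2"],
        "lake": ["l1", "l1", "l2"],
        "lake_type": ["crater", "crater", "tectonic"],
        "habitat": ["limnetic", "limnetic", "rocky"],
    })


def make_genotypes(matrix: np.ndarray, samples: pd.DataFrame,
                   allele_ids=None) -> GenotypeTable:
    allele_ids = allele_ids or [f"a{j + 1}" for j in range(matrix.shape[1])]
    m = pd.DataFrame(matrix, index=list(samples["individual_id"]), columns=allele_ids)
    return GenotypeTable(matrix=m, samples=samples)
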