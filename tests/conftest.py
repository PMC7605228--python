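import numpy as np
import pandas as pd
import pytest

from hexanull.config import SimulationConfig
from hexanull.synthetic import simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic dataset under the default study conditions."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_config():
    """A reduced dataset for fast structural tests."""
    return SimulationConfig(seed=7, n_genes=210, n_snps=400, n_progeny=30,
                            mean_library_size=200_000)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_bulk_table(n_per_chrom: dict[str, tuple[int, int]]) -> pd.DataFrame:
    """Construct a bulk SNP table with a prescribed number of maximally
    divergent (ED = sqrt(2)) and identical (ED = 0) SNPs per chromosome."""
    rows = []
    for chrom, (n_sig, n_null) in n_per_chrom.items():
        pos = 1
        for _ in range(n_sig):  # fertile fixed A, sterile fixed C
            rows.append((chrom, pos, "A", "C", 50, 0, 0, 0, 0, 50, 0, 0))
            pos += 10
        for _ in range(n_null):  # both bulks identical
            rows.append((chrom, pos, "A", "G", 25, 0, 25, 0, 25, 0, 25, 0))
            pos += 10
    cols = ["chrom", "pos", "ref", "alt",
            "fertile_A", "fertile_C", "fertile_G", "fertile_T",
            "sterile_A", "sterile_C", "sterile_G", "sterile_T"]
    return pd.DataFrame(rows, columns=cols)
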