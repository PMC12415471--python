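import numpy as np
import pandas as pd
import pytest

from cernakit import SimConfig, simulate_counts, simulate_target_tables


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down easy-regime study used across module tests."""
    return SimConfig(
        seed=11,
        n_mrna=120,
        n_lncrna=40,
        n_circrna=30,
        n_mirna=60,
        n_triplets=4,
        mirnas_per_triplet=4,
        circle_count=5,
        n_background_reads=300,
        chrom_length=40_000,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    matrices, truth = simulate_counts(small_config)
    table_a, table_b = simulate_target_tables(small_config, truth)
    return small_config, matrices, truth, table_a, table_b


@pytest.fixture
def toy_counts():
    """3 features x 4 samples with two samples per group."""
    counts = pd.DataFrame(
        [[10, 20, 10, 20], [100, 200, 100, 200], [1, 2, 1, 2]],
        index=pd.Index(["f1", "f2", "f3"], name="feature_id"),
        columns=["A1", "A2", "B1", "B2"],
    )
    from cernakit import CountMatrix

    return CountMatrix(
        counts=counts,
        classes=pd.Series("mRNA", index=counts.index),
        groups=pd.Series(["A", "A", "B", "B"], index=counts.columns),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
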