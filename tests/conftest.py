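import numpy as np
import pandas as pd
import pytest

from rhizotype import (
    AbundanceTable,
    SimulationConfig,
    simulate_dataset,
    to_relative_abundance,
)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset (44 samples, 745 genera)."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_features(default_dataset):
    table, meta, truth = default_dataset
    features = to_relative_abundance(table).data.T  # samples x taxa
    return features, meta.data["group"], truth


@pytest.fixture()
def small_table():
    return AbundanceTable(
        pd.DataFrame(
            [[5, 0, 2], [3, 1, 2], [2, 9, 6]],
            index=["t1", "t2", "t3"],
            columns=["s1", "s2", "s3"],
        ),
        unit="counts",
    )


def random_count_table(rng, n_taxa=6, n_samples=4, max_count=30):
    counts = rng.integers(0, max_count, size=(n_taxa, n_samples))
    counts[0, :] += 1  # no all-zero columns
    return AbundanceTable(
        pd.DataFrame(
            counts,
            index=[f"t{i}" for i in range(n_taxa)],
            columns=[f"s{j}" for j in range(n_samples)],
        ),
        unit="counts",
    )
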