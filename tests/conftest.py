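from pathlib import Path

import numpy as np
import pytest

import tickdecon as td

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_table():
    return td.read_count_table(DATA / "toy_counts.tsv")


@pytest.fixture(scope="session")
def toy_metadata():
    return td.read_metadata(DATA / "toy_metadata.tsv")


@pytest.fixture(scope="session")
def toy_taxonomy():
    return td.read_taxonomy(DATA / "toy_taxonomy.tsv")


@pytest.fixture(scope="session")
def sim_default():
    """One default-condition simulated dataset shared across tests."""
    return td.simulate_dataset(td.GeneratorConfig(seed=42))


def random_table(rng: np.random.Generator, n_otus=None, n_samples=None) -> td.CountTable:
    """Small random count table for property tests."""
    n_otus = n_otus or int(rng.integers(1, 20))
    n_samples = n_samples or int(rng.integers(2, 10))
    counts = rng.integers(0, 500, size=(n_otus, n_samples))
    return td.CountTable.from_arrays(
        counts,
        [f"O{i}" for i in range(n_otus)],
        [f"S{j}" for j in range(n_samples)],
    )
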