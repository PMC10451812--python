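import numpy as np
import pytest

from a1scape import BinnedGenome, SubcompartmentLabeling, generate_dataset
from a1scape.labels import LABELS


@pytest.fixture
def genome10():
    """One 500 kb chromosome at 50 kb: 10 bins."""
    return BinnedGenome(("chr1",), (500_000,), 50_000)


@pytest.fixture
def genome_multi():
    """Three small chromosomes (10 + 8 + 6 bins)."""
    return BinnedGenome(
        ("chr1", "chr2", "chr3"), (500_000, 400_000, 300_000), 50_000
    )


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic dataset shared across recovery tests."""
    return generate_dataset(seed=1)


def random_labeling(genome, rng, cell_type="ct", na_frac=0.0):
    labs = np.array(LABELS)[rng.integers(0, 8, genome.n_bins)].astype("<U2")
    if na_frac:
        labs[rng.random(genome.n_bins) < na_frac] = "NA"
    return SubcompartmentLabeling(genome, cell_type, labs)
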