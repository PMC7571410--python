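import numpy as np
import pytest

from rssnmf import make_block_dataset


@pytest.fixture(scope="session")
def clean_dataset():
    """Zero-noise block dataset: 5 groups x 20 marker genes x 10 cells."""
    return make_block_dataset(
        k_groups=5, genes_per_group=20, background_genes=0, cells_per_group=10,
        signal_mean=10.0, background_mean=0.0, noise_sd=0.0,
        outlier_fraction=0.0, outlier_magnitude=50.0, seed=1,
    )


@pytest.fixture(scope="session")
def outlier_dataset():
    """Same blocks with 10% of entries replaced by outliers of 5x signal."""
    return make_block_dataset(
        k_groups=5, genes_per_group=20, background_genes=0, cells_per_group=10,
        signal_mean=10.0, background_mean=0.0, noise_sd=0.0,
        outlier_fraction=0.10, outlier_magnitude=50.0, seed=1,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
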