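import numpy as np
import pandas as pd
import pytest

import txturn


@pytest.fixture(scope="session")
def small_dataset():
    """A small seeded turnover dataset shared by read-only tests."""
    model = txturn.TurnoverModel(n_windows=2_000, seed=11)
    return txturn.simulate_dataset(model)


@pytest.fixture(scope="session")
def small_mask(small_dataset):
    genomic = txturn.simulate_genomic_coverage(small_dataset.model, dropout=0.05)
    return txturn.common_genome_mask(genomic, genomic.taxa)


@pytest.fixture(scope="session")
def small_presence(small_dataset, small_mask):
    return txturn.binarize(small_dataset.counts, 1, small_mask)


@pytest.fixture
def toy_fragments():
    return pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr1", "chr2", "chr1"],
        "start": [100, 150, 390, 10, 950],
        "end": [260, 350, 410, 90, 1050],
        "sample_id": ["s1", "s1", "s2", "s2", "s1"],
    })


@pytest.fixture
def toy_windows():
    return txturn.make_windows({"chr1": 1000, "chr2": 400}, 200)
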