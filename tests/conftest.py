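import pandas as pd
import pytest

from tricoord import data_io, indices, synthetic_data


@pytest.fixture(scope="session")
def default_dataset():
    """One dataset at the generator's default study conditions."""
    return synthetic_data.generate(synthetic_data.SyntheticTruth(seed=1))


@pytest.fixture(scope="session")
def small_truth():
    """A fast, smaller configuration for unit-level checks."""
    return synthetic_data.SyntheticTruth(n_genes=2000, n_groups=8, group_size=20,
                                         n_pairs=600, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_truth):
    return synthetic_data.generate(small_truth)


@pytest.fixture(scope="session")
def small_index_table(small_dataset):
    filtered, _ = data_io.filter_expressed(small_dataset.profile)
    return indices.compute_indices(filtered)


@pytest.fixture()
def toy_profile():
    """Four genes with hand-pickable values (one gene has a zero TR)."""
    values = pd.DataFrame(
        {"tr": [1.0, 1.0, 4.0, 0.0],
         "ra": [1.0, 2.0, 2.0, 5.0],
         "ta": [1.0, 4.0, 1.0, 5.0]},
        index=pd.Index(["G1", "G2", "G3", "G4"], name="gene_id"))
    return data_io.ExpressionProfile(values=values)
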