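import numpy as np
import pytest

from cellhash import CellDatabase, ExpressionMatrix, SynthSpec, make_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Three well-separated clusters, 500 genes x 150 cells."""
    spec = SynthSpec(
        n_genes=500,
        n_cells=150,
        n_clusters=3,
        marker_genes_per_cluster=50,
        seed=42,
    )
    return make_dataset(spec)


@pytest.fixture(scope="session")
def small_db(small_dataset):
    X, labels, _ = small_dataset
    db = CellDatabase(
        n_bits=64, n_hashes=2, n_dims=20, store_counts=True, random_state=7
    )
    return db.fit(X, y=labels)


@pytest.fixture
def tiny_matrix():
    counts = np.array(
        [
            [5, 0, 2],
            [1, 3, 0],
            [0, 0, 7],
            [2, 2, 2],
        ]
    )
    return ExpressionMatrix(counts, ["g1", "g2", "g3", "g4"], ["c1", "c2", "c3"])
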