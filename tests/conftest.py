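import numpy as np
import pytest

import morphoctx as m


@pytest.fixture(scope="session")
def small_cohort():
    """Feature-path cohort: 16 samples, ~60 cells each, strong separation."""
    cfg = m.demo_preset(seed=7, n_samples=16, cells_per_slide=60)
    return m.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_dictionary(small_cohort):
    """64-atom dictionary trained on the small cohort (sparsity 8)."""
    return m.learn_from_tables(
        small_cohort.features, rate=100, n_atoms=64, sparsity=8, n_iter=5, seed=0
    )


@pytest.fixture(scope="session")
def small_contexts(small_cohort, small_dictionary):
    return m.encode_cohort(small_cohort.features, small_dictionary)


@pytest.fixture()
def orthogonal_dictionary():
    """4 orthogonal unit atoms in 15 dimensions (axis vectors)."""
    atoms = np.zeros((4, 15))
    for i in range(4):
        atoms[i, i] = 1.0
    return m.CMBDictionary(atoms=atoms, sparsity=2)


def planted_contexts(n_per: int = 50, sep: float = 6.0, dim: int = 16, seed: int = 0):
    """Two spherical clusters with centroid separation ``sep`` x within-SD."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, (n_per, dim))
    b = rng.normal(0.0, 1.0, (n_per, dim)) + sep / np.sqrt(dim)
    X = np.vstack([a, b])
    labels = np.repeat([1, 2], n_per)
    return X, labels
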