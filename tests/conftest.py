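import warnings

import numpy as np
import pytest

import snfimc as s


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted dataset shared by pipeline-level tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return s.generate_dataset(nd=25, nm=30, rank=3, density=0.1, noise=0.1,
                                  seed=7)


@pytest.fixture(scope="session")
def small_inputs(small_dataset):
    """(assoc, disease semantic similarity, miRNA functional similarity)."""
    sem = s.semantic_similarity_matrix(
        small_dataset.disease_dag, small_dataset.assoc.disease_ids
    )
    return small_dataset.assoc, sem, small_dataset.mirna_functional


def random_similarity(n, rng, ids=None):
    """Random symmetric nonnegative similarity with unit diagonal."""
    M = rng.uniform(size=(n, n))
    M = (M + M.T) / 2.0
    np.fill_diagonal(M, 1.0)
    return s.SimilarityMatrix(M, ids or [f"e{i}" for i in range(n)])
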