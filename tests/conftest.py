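import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from metaphorspace.corpus import (
    PMIConfig,
    build_vocabulary,
    clean_corpus,
    compute_pmi,
    count_cooccurrences,
)
from metaphorspace.fixtures import micro_corpus
from metaphorspace.subspace import Subspace

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def micro_sentences():
    return list(clean_corpus(micro_corpus()))


@pytest.fixture(scope="session")
def micro_vocab(micro_sentences):
    return build_vocabulary(micro_sentences, 50)


@pytest.fixture(scope="session")
def micro_table(micro_sentences, micro_vocab):
    return count_cooccurrences(micro_sentences, micro_vocab, window=2)


@pytest.fixture(scope="session")
def micro_pmi(micro_table):
    # small smoothing keeps desk-scale PMI values well away from zero
    return compute_pmi(micro_table, PMIConfig(smoothing_a=10.0))


def make_random_subspace(rng: np.random.Generator, k: int | None = None) -> Subspace:
    """A structurally valid random subspace: M/X/C derived from a small
    random non-negative 'vocabulary' that includes V and N."""
    k = int(k or rng.integers(3, 9))
    n_vocab = int(rng.integers(4, 9))
    vecs = rng.random((n_vocab, k)) * (rng.random((n_vocab, k)) < 0.7)
    vecs[0, int(rng.integers(k))] += 0.5  # V, N non-zero
    vecs[1, int(rng.integers(k))] += 0.5
    V, N = vecs[0], vecs[1]
    M = np.zeros(k)
    X = np.zeros(k)
    for j in range(k):
        nz = vecs[:, j][vecs[:, j] > 0]
        if nz.size:
            M[j] = nz.mean()
            X[j] = nz.max()
    C = np.full(k, M.mean())
    dims = [f"d{j}" for j in range(k)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return Subspace(dims, V, N, M, X, C)


@pytest.fixture
def random_subspace_factory():
    return make_random_subspace
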