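import numpy as np
import pytest

from acrsift import LibrarySpec, VectorMap, build_library, vector_sequence


@pytest.fixture(scope="session")
def vmap():
    return VectorMap()


@pytest.fixture(scope="session")
def vector_seq(vmap):
    return vector_sequence(vmap, seed=0)


@pytest.fixture()
def small_model(vmap):
    """A 20-clone library with a mix of clone classes."""
    spec = LibrarySpec(n_unique_clones=20, acr_frequency=0.1, lof_rate=0.05,
                       site_mutation_rate=0.1, recombination_rate=0.1,
                       insert_length_mean=800, insert_length_sd=100, seed=11)
    return build_library(spec, vmap)


def random_dna(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
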