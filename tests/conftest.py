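import pytest

from sccref import ToyGenomeSpec, build_kmer_index, make_toy_genome


@pytest.fixture(scope="session")
def toy():
    """One toy genome shared across the session (deterministic, seed 17)."""
    return make_toy_genome(ToyGenomeSpec(seed=17))


@pytest.fixture(scope="session")
def default_index(toy):
    return build_kmer_index(toy.genome)
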