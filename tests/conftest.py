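import pytest

from envpath.simulate import make_synthetic_community


@pytest.fixture(scope="session")
def community():
    """Default synthetic community shared by read-only tests."""
    return make_synthetic_community(n_genomes=10, n_pathways=40, seed=0)


@pytest.fixture(scope="session")
def small_community():
    return make_synthetic_community(
        n_genomes=3, n_pathways=10, seed=7, core_pathways=3, accessory_per_genome=2
    )
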