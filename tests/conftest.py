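import pytest

from trfspace import SyntheticGenomeSpec, generate_genome, generate_reads


@pytest.fixture(scope="session")
def fixture100k():
    """Default synthetic genome: 100 kb, 6 tRNAs (2 intronic), 10 partial
    copies, 3 lookalikes, 3 CCA decoys."""
    return generate_genome(SyntheticGenomeSpec(seed=11))


@pytest.fixture(scope="session")
def reads1000(fixture100k):
    """1000 reads sampled from the default fixture, with recomputed truth."""
    return generate_reads(fixture100k, n_reads=1000, seed=12)


@pytest.fixture(scope="session")
def small_fixture():
    """A 20 kb fixture small enough for brute-force recomputation in tests."""
    return generate_genome(
        SyntheticGenomeSpec(
            genome_length=20_000,
            n_trnas=3,
            n_intronic_trnas=1,
            n_partial_copies=3,
            n_lookalikes=1,
            n_cca_decoys=1,
            seed=7,
        )
    )
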