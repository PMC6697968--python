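import pytest

from agorip.io import Read
from agorip.simulate import LibraryModel, ReferenceConfig, simulate_reference


@pytest.fixture(scope="session")
def small_bundle():
    """Compact reference: 1 x 50 kb chromosome, 5 loci per class, 5 hairpins."""
    config = ReferenceConfig(
        chrom_lengths={"chr1": 50_000},
        n_loci_21=5,
        n_loci_24=5,
        phases_21=10,
        phases_24=10,
        n_hairpins=5,
    )
    return simulate_reference(config, seed=1)


@pytest.fixture(scope="session")
def library_model():
    return LibraryModel()


def make_read(seq, qual=None, rid="r"):
    return Read(rid, seq, tuple(qual if qual is not None else [38] * len(seq)))


@pytest.fixture()
def read_factory():
    return make_read
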