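import numpy as np
import pytest

from rnpbscan import (
    ReferenceDB,
    ReferenceRecord,
    ScanParams,
    ScoringScheme,
    SimSpec,
    make_reference_set,
    plant_loci,
)


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()


@pytest.fixture(scope="session")
def sim_spec() -> SimSpec:
    return SimSpec(seed=11, genome_length=30_000, n_plants=3, sub_rate=0.05)


@pytest.fixture(scope="session")
def ref_db(sim_spec) -> ReferenceDB:
    """5-type synthetic reference database (2 families x 5 members per type)."""
    return make_reference_set(sim_spec)


@pytest.fixture(scope="session")
def planted_genome(sim_spec, ref_db):
    return plant_loci(sim_spec, ref_db)


@pytest.fixture()
def tiny_db() -> ReferenceDB:
    """Two hand-made records long enough to pass length validation."""
    rng = np.random.default_rng(7)
    bases = np.frombuffer(b"ACGT", dtype=np.int8)

    def rand(n):
        return bases[rng.integers(0, 4, n)].tobytes().decode()

    return ReferenceDB(
        [
            ReferenceRecord("refA", rand(300), "A", "bacteria", "unit test"),
            ReferenceRecord("refT", rand(200), "T", "archaea", "unit test"),
        ]
    )


def random_dna_str(rng: np.random.Generator, n: int) -> str:
    bases = np.frombuffer(b"ACGT", dtype=np.int8)
    return bases[rng.integers(0, 4, n)].tobytes().decode()
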