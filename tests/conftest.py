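import numpy as np
import pytest

import popscan as p


@pytest.fixture(scope="session")
def small_community():
    """A 50 kbp community with one deleted gene; shared read-only."""
    spec = p.CommunitySimSpec(
        genome_length=50_000,
        n_genes=40,
        mean_depth=5,
        rng_seed=11,
        background_fraction=0.0,
    )
    return p.simulate_community(spec)


@pytest.fixture(scope="session")
def small_records(small_community):
    return p.recruit_reads(small_community.reads, small_community.reference)


@pytest.fixture(scope="session")
def small_profile(small_community, small_records):
    return p.build_profile(small_records, small_community.reference)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
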