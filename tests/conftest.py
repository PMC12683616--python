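import numpy as np
import pytest

import flashforest as ff


@pytest.fixture(scope="session")
def species_frame():
    return ff.gen_species(ff.FixtureSpec(seed=0))


@pytest.fixture(scope="session")
def species_table(species_frame):
    return ff.SpeciesTable.from_frame(species_frame)


@pytest.fixture(scope="session")
def forcing():
    return ff.gen_forcing(0)


@pytest.fixture
def small_grid():
    return ff.build_grid(30, 30, 50)


@pytest.fixture
def traits():
    """One plain species record used by scalar-path tests."""
    return ff.SpeciesTraits(
        species_id="test",
        lma=100.0,
        wsg=0.6,
        leaf_n=2.5,
        leaf_p=0.15,
        allom_a=40.0,
        allom_b=1.0,
        allom_k=20.0,
        maturity_dbh=10.0,
        delta_i=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
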