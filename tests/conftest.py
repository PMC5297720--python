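import pytest

from metsim.species import load_species_db
from metsim.speciation import default_families


@pytest.fixture(scope="session")
def db():
    return load_species_db()


@pytest.fixture(scope="session")
def families(db):
    return default_families(db)
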