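import pytest

from rpe.fixtures import COMPOUNDS, flavor_network_db
from rpe.rules import extract_rules_for_db


@pytest.fixture(scope="session")
def network():
    """(ReactionDB, FixtureManifest) for the flavor network."""
    return flavor_network_db()


@pytest.fixture(scope="session")
def db(network):
    return network[0]


@pytest.fixture(scope="session")
def manifest(network):
    return network[1]


@pytest.fixture(scope="session")
def default_rules(network):
    db, manifest = network
    return extract_rules_for_db(
        db, radius=1, exclude_ids=manifest.default_profile_excluded
    )


@pytest.fixture(scope="session")
def compounds():
    return COMPOUNDS
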