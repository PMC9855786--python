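import pytest

import tdgfquant as tq


@pytest.fixture(scope="session")
def catalog():
    """Default 4-group single-marker catalog."""
    return tq.load_default_catalog()


@pytest.fixture(scope="session")
def full_catalog():
    """All 8 shipped markers."""
    return tq.load_default_catalog(singles_only=False)


@pytest.fixture(scope="session")
def default_sim(catalog):
    """One default-condition simulated experiment (seed 7), shared
    read-only across tests."""
    spec = tq.CommunitySpec(seed=7)
    community = tq.generate_community(spec, catalog)
    sim = tq.simulate_expression(spec, community, catalog)
    return spec, community, sim


@pytest.fixture(scope="session")
def default_hits(catalog, default_sim):
    _, community, _ = default_sim
    return tq.search_tdgfs(catalog, community.contigs)
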