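import pytest

from netpharm.chem import curate_compounds
from netpharm.networks import build_bipartite, expand_disease_network, filter_ppi, intersect
from netpharm.synthetic import cki_fixture


@pytest.fixture(scope="session")
def bundle():
    """The deterministic CKI / lung-cancer case-study bundle."""
    return cki_fixture(verify=False)


@pytest.fixture(scope="session")
def curated(bundle):
    return curate_compounds(bundle.compounds)


@pytest.fixture(scope="session")
def bipartite_net(bundle, curated):
    return build_bipartite(curated, bundle.ct_edges)


@pytest.fixture(scope="session")
def disease_net(bundle):
    return expand_disease_network(
        bundle.disease_seeds, filter_ppi(bundle.ppi_edges, 0.7, strict=True)
    )


@pytest.fixture(scope="session")
def intersection(bipartite_net, disease_net):
    return intersect(bipartite_net, disease_net)
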