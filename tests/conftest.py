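import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from lncgba import (
    CoexpressionNetworkBuilder,
    FunctionalAnnotator,
    split_by_biotype,
)
from lncgba.synthetic import FixtureConfig, generate_fixture


@pytest.fixture(scope="session")
def bundle():
    """One default planted-module fixture shared across tests."""
    return generate_fixture(FixtureConfig(seed=7))


@pytest.fixture(scope="session")
def network(bundle):
    lnc, coding = split_by_biotype(bundle.expression, bundle.catalog)
    return CoexpressionNetworkBuilder().fit(lnc, coding).network_


@pytest.fixture(scope="session")
def annotator(bundle, network):
    universe = bundle.catalog.genes_of("protein_coding")
    return FunctionalAnnotator().fit(
        network, bundle.annotations, bundle.pathways, universe, dag=bundle.dag
    )
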