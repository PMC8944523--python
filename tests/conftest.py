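import pytest

from genefamkit.identify import DEFAULT_DOMAIN_CONSENSUS, DomainModel, identify_family
from genefamkit.synthetic import SyntheticConfig, generate_bundle


@pytest.fixture(scope="session")
def domain_model():
    return DomainModel.from_consensus(DEFAULT_DOMAIN_CONSENSUS, name="GPX")


@pytest.fixture(scope="session")
def bundle():
    """One synthetic species bundle at the default study conditions."""
    return generate_bundle(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def species(bundle):
    return bundle.to_species_bundle()


@pytest.fixture(scope="session")
def members(species, domain_model):
    return identify_family(species, domain_model, "Gso", "GPX")
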