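import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from longinet.network import build_network
from longinet.simulate import GeneratorConfig, gen_dti_network


@pytest.fixture
def toy_network():
    """Two drugs, three targets, with gene symbols attached."""
    genes = {"T1": "GENE1", "T2": "GENE2", "T3": "GENE3"}
    return build_network(
        [("d1", "T1"), ("d1", "T2"), ("d2", "T2"), ("d2", "T3")],
        "experimental",
        genes,
    )


@pytest.fixture(scope="session")
def planted_fixture():
    """The default planted study: 200 drugs, 20 planted at pi = 0.5."""
    return gen_dti_network(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def planted_profiles(planted_fixture):
    d = planted_fixture
    return {
        drug: {d.target_gene_map[t] for t in d.net.drug_targets(drug)}
        for drug in d.net.drugs
    }
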