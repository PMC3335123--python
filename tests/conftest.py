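import networkx as nx
import pytest

from coexnet import ModuleSpec, SyntheticConfig, generate_multi_study


@pytest.fixture(scope="session")
def default_design():
    """Default 3-study design: one shared and one private module per study."""
    return SyntheticConfig(seed=11)


@pytest.fixture(scope="session")
def three_studies(default_design):
    return generate_multi_study(default_design)


@pytest.fixture(scope="session")
def two_module_design():
    return SyntheticConfig(
        n_genes=60,
        n_samples_per_study=80,
        shared_modules=(ModuleSpec(12, 0.9), ModuleSpec(10, 0.85)),
        private_modules_per_study=(ModuleSpec(8, 0.9),),
        seed=5,
    )


@pytest.fixture()
def ring_of_cliques():
    return nx.ring_of_cliques(4, 5)


@pytest.fixture()
def two_triangles():
    return nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
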