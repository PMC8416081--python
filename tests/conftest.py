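import pytest

from treehole.ontology import load_default_graph
from treehole.rules import load_default_negation, load_default_rules


@pytest.fixture(scope="session")
def graph():
    return load_default_graph()


@pytest.fixture(scope="session")
def rules():
    return load_default_rules()


@pytest.fixture(scope="session")
def neg_config():
    return load_default_negation()
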