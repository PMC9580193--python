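import pytest

from vaxalign import build_dictionary, build_mini_ontology, classify


@pytest.fixture(scope="session")
def mini_onto():
    return build_mini_ontology()


@pytest.fixture(scope="session")
def mini_index(mini_onto):
    return classify(mini_onto)


@pytest.fixture(scope="session")
def mini_dict(mini_onto):
    return build_dictionary(mini_onto)
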