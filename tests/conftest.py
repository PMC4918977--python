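import pytest

import gpml2rdf as g
from gpml2rdf import fixtures


@pytest.fixture(scope="session")
def glucose_model():
    return g.parse_gpml(fixtures.paper_fixture("glucose_node"))


@pytest.fixture(scope="session")
def glucose_gpml_graph(glucose_model):
    return g.emit_gpml_layer(glucose_model)


@pytest.fixture(scope="session")
def default_rules():
    return g.default_rules()


@pytest.fixture(scope="session")
def corpus():
    """Small deterministic corpus: (parsed models, GPML bytes, mapping TSV, manifest)."""
    config = fixtures.GeneratorConfig(seed=11, n_pathways=8)
    files, mapping_tsv, manifest = fixtures.generate_corpus(config)
    models = [g.parse_gpml(data) for data in files]
    return models, files, mapping_tsv, manifest


@pytest.fixture(scope="session")
def corpus_models(corpus):
    return corpus[0]


@pytest.fixture(scope="session")
def corpus_manifest(corpus):
    return corpus[3]
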