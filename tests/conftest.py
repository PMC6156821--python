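import pytest

from litnet.fixtures import builtin_kb, generate_fixture_corpus, verbatim_fixtures
from litnet.grammar import load_default_grammar
from litnet.pipeline import extract_document


@pytest.fixture(scope="session")
def kb():
    return builtin_kb()


@pytest.fixture(scope="session")
def grammar():
    return load_default_grammar()


@pytest.fixture(scope="session")
def corpus():
    return generate_fixture_corpus(seed=7) + verbatim_fixtures()


@pytest.fixture(scope="session")
def extractions(corpus, kb, grammar):
    """name -> (fixture, ExtractionResult) for the whole fixture corpus."""
    out = {}
    for fx in corpus:
        out[fx.name] = (fx, extract_document(fx.document, kb, grammar))
    return out


def fixture_by_name(corpus, name):
    for fx in corpus:
        if fx.name == name:
            return fx
    raise KeyError(name)
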