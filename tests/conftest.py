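import pytest

from genelink.fixtures import FixtureConfig, make_fixture_corpus


@pytest.fixture(scope="session")
def corpus():
    """Mixed corpus: variations, one ambiguous plant per doc, decoys."""
    return make_fixture_corpus(seed=7, n_docs=12)


@pytest.fixture(scope="session")
def exact_corpus():
    """Exact-name plants only: no variations, no ambiguity, no decoys."""
    cfg = FixtureConfig(variations=False, ambiguous=False, decoys=False)
    return make_fixture_corpus(seed=11, n_docs=10, config=cfg)


@pytest.fixture(scope="session")
def gene_index(corpus):
    return corpus.gene_index()


@pytest.fixture(scope="session")
def lexicon(corpus, gene_index):
    return corpus.species_lexicon(gene_index)
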