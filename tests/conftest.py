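import pytest

from fusemine.lexicon import default_lexicon
from fusemine.textproc import Sentence, categorize_tokens, tokenize


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture
def make_sentence():
    def _make(text, doc_id="doc1", index=0):
        return Sentence(doc_id=doc_id, index=index, text=text, span=(0, len(text)))

    return _make


@pytest.fixture
def tagged_tokens(lexicon):
    """Tokenize and categorize a sentence text in one step."""

    def _tag(text):
        tokens = tokenize(text)
        categorize_tokens(tokens, lexicon)
        return tokens

    return _tag
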