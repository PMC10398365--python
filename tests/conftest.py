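import pytest

from cessalex import (Corpus, Post, default_emotion_lexicon,
                      default_time_lexicon)
from cessalex.lexicons import Lexicon


@pytest.fixture(scope="session")
def emotion_lexicon():
    return default_emotion_lexicon()


@pytest.fixture(scope="session")
def time_lexicon():
    return default_time_lexicon()


@pytest.fixture
def tiny_lexicon():
    return Lexicon("tiny", {
        "pride": frozenset({"proud"}),
        "anxiety": frozenset({"anxious"}),
        "joy": frozenset({"happy", "glad"}),
    })


def make_corpus(bodies, forum="f", window=None, abstinence=None,
                authors=None):
    """Corpus with given bodies, newest first, 1-minute spacing."""
    n = len(bodies)
    posts = [Post(forum=forum,
                  author=(authors[i] if authors else f"u{i}"),
                  created_utc=1_000_000.0 - 60 * i,
                  title=f"t{i}", body=b,
                  abstinence_days=(abstinence[i] if abstinence else None))
             for i, b in enumerate(bodies)]
    return Corpus(forum, posts, window if window is not None else n)


@pytest.fixture
def corpus_factory():
    return make_corpus
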