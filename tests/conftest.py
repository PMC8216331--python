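import pytest

from depsym import synth
from depsym.pipeline import RunConfig, build_default_lexicon
from depsym.tweets import classify_tweets


@pytest.fixture(scope="session")
def default_lexicon():
    """The shipped lexicon: default seeds expanded over the default
    synthetic enrichment corpus."""
    return build_default_lexicon()


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study conditions for generator-backed tests."""
    return synth.SyntheticConfig(n_respondents=4000, n_users=8000, rng_seed=123)


@pytest.fixture(scope="session")
def tweet_stream(small_config, default_lexicon):
    return synth.generate_tweets(small_config, default_lexicon)


@pytest.fixture(scope="session")
def classified(small_config, default_lexicon, tweet_stream):
    return classify_tweets(tweet_stream, default_lexicon,
                           window=small_config.window())
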