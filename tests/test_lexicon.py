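"""Seed sets, embedding training, expansion and exact-match semantics."""

import numpy as np
import pytest

from depsym.lexicon import (DEFAULT_SEEDS, EmbeddingSpace, SeedSet,
                            SymptomLexicon, build_seed_sets, expand_lexicon,
                            match_keywords, normalize_keyword, tokenize,
                            train_embedding)


def brute_force_expansion(seeds, space, tau, k):
    """Independent oracle: full-vocabulary cosine scan with numpy only."""
    unit = space.vectors / np.linalg.norm(space.vectors, axis=1, keepdims=True)
    idx = {t: i for i, t in enumerate(space.vocabulary)}
    out = {}
    for ss in seeds:
        seed_tokens = {w.replace(" ", "_") for w in ss.words}
        best = {}
        for w in sorted(ss.words):
            tok = w.replace(" ", "_")
            if tok not in idx:
                continue
            sims = unit @ unit[idx[tok]]
            cands = sorted(
                ((float(sims[i]), t) for i, t in enumerate(space.vocabulary)
                 if t not in seed_tokens and sims[i] >= tau),
                key=lambda p: (-p[0], p[1]))
            for score, tok2 in cands[:k]:
                word = tok2.replace("_", " ")
                if word not in ss.words:
                    best[word] = max(best.get(word, -2.0), score)
        out[ss.symptom] = set(best)
    return out


class TestSeedSets:
    def test_default_depressed_mood_triple(self):
        seeds = {s.symptom: s.words for s in build_seed_sets()}
        assert seeds["depressed_mood"] == {
            "niedergeschlagenheit", "schwermut", "hoffnungslosigkeit"}

    def test_every_symptom_covered(self):
        assert set(DEFAULT_SEEDS) == {s.symptom for s in build_seed_sets()}

    @pytest.mark.parametrize("words,expected", [
        (["X"], {"x"}),
        (["a", "A"], {"a"}),
        (["  Schlechte   Stimmung "], {"schlechte stimmung"}),
    ])
    def test_normalization(self, words, expected):
        [ss] = build_seed_sets({"depressed_mood": words})
        assert ss.words == expected

    def test_empty_list_errors(self):
        with pytest.raises(ValueError, match="no keywords"):
            build_seed_sets({"depressed_mood": []})

    def test_unknown_symptom_errors(self):
        with pytest.raises(ValueError, match="unknown symptom"):
            SeedSet("anxiety", frozenset({"angst"}))


class TestEmbedding:
    def test_perfectly_associated_pair_cosine_one(self):
        # two tokens with identical co-occurrence profiles (each appears
        # only next to the shared context token) are perfectly associated
        space = train_embedding(["aa cc", "bb cc"] * 5, dim=2, min_count=1)
        sims = space.cosine_similarities("aa")
        assert sims[space.vocabulary.index("bb")] == pytest.approx(1.0)

    def test_min_count_filters_rare_token(self):
        space = train_embedding(["aa bb", "aa bb", "aa bb zz"], dim=1, min_count=2)
        assert "zz" not in space.vocabulary

    def test_dim_exceeding_vocabulary_errors(self):
        with pytest.raises(ValueError, match="dim"):
            train_embedding(["aa bb"] * 3, dim=10, min_count=1)

    def test_training_is_deterministic(self):
        corpus = ["aa bb cc", "bb cc dd", "cc dd aa", "dd aa bb"] * 3
        s1 = train_embedding(corpus, dim=3, min_count=1)
        s2 = train_embedding(corpus, dim=3, min_count=1)
        assert s1.vocabulary == s2.vocabulary
        np.testing.assert_array_equal(s1.vectors, s2.vectors)

    def test_phrase_joined_as_single_token(self):
        corpus = ["schlechte stimmung heute", "schlechte stimmung immer"]
        space = train_embedding(corpus, dim=1, min_count=1,
                                phrases=["schlechte stimmung"])
        assert "schlechte_stimmung" in space.vocabulary
        assert "schlechte" not in space.vocabulary


class TestExpansion:
    @pytest.fixture()
    def toy_space(self):
        # handcrafted 2-d space: seed along e1, candidates at known cosines
        words = ["seed", "a", "b", "c", "d", "e", "far"]
        angles = [0.0, 0.2, 0.3, 0.3, 0.5, 0.7, 2.5]
        vecs = np.array([[np.cos(t), np.sin(t)] for t in angles])
        return EmbeddingSpace(vocabulary=words, vectors=vecs)

    def test_top_k_with_lexicographic_ties(self, toy_space):
        seeds = [SeedSet("depressed_mood", frozenset({"seed"}))]
        lex = expand_lexicon(seeds, toy_space, tau=0.5, k=3)
        expanded = lex.keywords("depressed_mood") - {"seed"}
        # cosines: a=.980, b=c=.955 (tie -> lexicographic), d=.878, e=.765
        assert expanded == {"a", "b", "c"}

    def test_tau_one_returns_seeds_only(self, toy_space):
        seeds = [SeedSet("depressed_mood", frozenset({"seed"}))]
        lex = expand_lexicon(seeds, toy_space, tau=1.0, k=10)
        assert lex.keywords("depressed_mood") == {"seed"}

    def test_absent_seed_contributes_nothing(self, toy_space):
        seeds = [SeedSet("fatigue_energy_loss", frozenset({"unbekannt"}))]
        lex = expand_lexicon(seeds, toy_space, tau=0.0, k=10)
        assert lex.keywords("fatigue_energy_loss") == {"unbekannt"}

    def test_deny_list_removes_and_allow_list_adds(self, toy_space):
        seeds = [SeedSet("depressed_mood", frozenset({"seed"}))]
        lex = expand_lexicon(seeds, toy_space, tau=0.5, k=3,
                             allow={"depressed_mood": ["kurated"]}, deny=["a"])
        expanded = lex.keywords("depressed_mood") - {"seed"}
        assert "a" not in expanded and "kurated" in expanded

    def test_tau_monotonicity(self, default_lexicon, small_config):
        from depsym import synth
        from depsym.pipeline import RunConfig, _collect_phrases
        seeds = build_seed_sets()
        corpus = synth.generate_corpus(small_config, seeds)
        space = train_embedding(corpus, dim=40, min_count=2,
                                phrases=_collect_phrases(seeds, RunConfig()))
        previous = None
        for tau in (1.0, 0.8, 0.6, 0.4, 0.2, 0.0):
            lex = expand_lexicon(seeds, space, tau=tau, k=100)
            current = {s: lex.keywords(s) for s in lex.symptoms()}
            if previous is not None:
                for s in current:
                    assert previous[s] <= current[s], f"tau drop lost keywords for {s}"
            previous = current

    def test_matches_brute_force_scan(self, toy_space):
        seeds = [SeedSet("depressed_mood", frozenset({"seed"}))]
        for tau, k in [(0.0, 2), (0.5, 3), (0.9, 10), (0.99, 1)]:
            lex = expand_lexicon(seeds, toy_space, tau=tau, k=k)
            oracle = brute_force_expansion(seeds, toy_space, tau, k)
            assert lex.keywords("depressed_mood") - {"seed"} == oracle["depressed_mood"]

    def test_expanded_scores_at_least_tau(self, default_lexicon):
        for sym in default_lexicon.symptoms():
            for e in default_lexicon.entries[sym]:
                if e.provenance == "expanded":
                    assert e.score is None or e.score >= 0.4

    def test_json_round_trip(self, default_lexicon):
        text = default_lexicon.to_json()
        back = SymptomLexicon.from_json(text)
        for s in default_lexicon.symptoms():
            assert back.keywords(s) == default_lexicon.keywords(s)
            assert back.seed_keywords(s) == default_lexicon.seed_keywords(s)


class TestMatching:
    @pytest.mark.parametrize("text,expected", [
        ("Ja schon...Ich fühle mich immer so energielos.", {"fatigue_energy_loss"}),
        ("#Hoffnungslosigkeit überall", {"depressed_mood"}),
        ("Energie", set()),          # no substring matching
        ("", set()),
        ("SCHWERMUT!!!", {"depressed_mood"}),
    ])
    def test_examples(self, text, expected, default_lexicon):
        assert match_keywords(text, default_lexicon) == expected

    def test_multiword_requires_contiguous_run(self, default_lexicon):
        assert "depressed_mood" in match_keywords(
            "heute mal wieder schlechte Stimmung", default_lexicon)
        assert "depressed_mood" not in match_keywords(
            "schlechte und gute Stimmung", default_lexicon)

    def test_seed_matches_subset_of_expanded_matches(self, default_lexicon):
        seeds_only = SymptomLexicon.from_seeds(build_seed_sets())
        texts = [
            "Ich bin so bedrückt heute",
            "Schwermut liegt über allem",
            "völlig ausgelaugt und kraftlos",
            "Das Wetter ist schön",
        ]
        for t in texts:
            assert match_keywords(t, seeds_only) <= match_keywords(t, default_lexicon)

    def test_tokenizer_strips_hashtags_and_lowercases(self):
        assert tokenize("#Müdigkeit, und MEHR!") == ["müdigkeit", "und", "mehr"]
        assert normalize_keyword("  Keine   LUST ") == "keine lust"
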