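"""Symptom keyword lexicons: seed sets, embedding-based expansion, matching.

Each of the five symptom categories is anchored by a small set of manually
chosen German seed keywords taken from the wording of the corresponding
questionnaire item.  The seed sets are then enriched with semantically
related words discovered in a depression-forum-style corpus: words are
embedded by factorizing a positive-PMI-weighted co-occurrence matrix with a
truncated SVD, and for every seed the nearest cosine neighbours above a
similarity threshold join the lexicon.  Texts are matched against the
resulting lexicon by exact token-sequence match (lowercased, hashtag
markers stripped, no stemming) -- a deliberately strict contract, so that
"Energie" never matches a lexicon entry "energielos".
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from depsym.symptoms import SYMPTOMS

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"\w+")


def tokenize(text: str) -> list[str]:
    """Unicode word tokens, lowercased; '#' is not a word character, so
    hashtags tokenize to their bare word form."""
    return [t.lower() for t in _TOKEN_RE.findall(text)]


def normalize_keyword(word: str) -> str:
    """Canonical keyword form: lowercase, single-spaced token sequence."""
    return " ".join(tokenize(word))


# --------------------------------------------------------------------------
# seed sets

#: Default seed keywords per symptom.  The depressed-mood seeds are the
#: published triple (dejection / melancholy / hopelessness); the remaining
#: sets follow the same item-anchored construction.
DEFAULT_SEEDS: dict[str, tuple[str, ...]] = {
    "diminished_interest": ("interessenverlust", "lustlosigkeit", "keine lust"),
    "depressed_mood": ("niedergeschlagenheit", "schwermut", "hoffnungslosigkeit"),
    "insomnia_hypersomnia": ("schlaflosigkeit", "schlafprobleme", "insomnie"),
    "fatigue_energy_loss": ("müdigkeit", "erschöpfung", "energielos"),
    "worthlessness_guilt": ("wertlosigkeit", "schuldgefühle", "versagen"),
}


@dataclass(frozen=True)
class SeedSet:
    """Manually curated keywords anchoring one symptom category."""

    symptom: str
    words: frozenset[str]

    def __post_init__(self) -> None:
        if self.symptom not in SYMPTOMS:
            raise ValueError(f"unknown symptom {self.symptom!r}; expected one of {SYMPTOMS}")
        if not self.words:
            raise ValueError(f"empty seed set for {self.symptom}")


def build_seed_sets(item_definitions: Mapping[str, Iterable[str]] | None = None) -> list[SeedSet]:
    """Normalize per-symptom keyword lists into :class:`SeedSet` objects.

    With no argument, returns the package's default seed table.  Duplicate
    words collapse after normalization ("A" and "a" are one keyword).
    """
    defs = DEFAULT_SEEDS if item_definitions is None else item_definitions
    out = []
    for symptom, words in defs.items():
        norm = frozenset(normalize_keyword(w) for w in words if normalize_keyword(w))
        if not norm:
            raise ValueError(f"no keywords supplied for symptom {symptom!r}")
        out.append(SeedSet(symptom=symptom, words=norm))
    return out


# --------------------------------------------------------------------------
# embedding space

def _phrase_token(keyword: str) -> str:
    return keyword.replace(" ", "_")


def _join_phrases(tokens: list[str], phrases: set[tuple[str, ...]]) -> list[str]:
    """Merge known multi-word phrases into single underscore-joined tokens."""
    if not phrases:
        return tokens
    max_len = max(len(p) for p in phrases)
    out: list[str] = []
    i = 0
    n = len(tokens)
    while i < n:
        merged = False
        for ln in range(min(max_len, n - i), 1, -1):
            cand = tuple(tokens[i:i + ln])
            if cand in phrases:
                out.append("_".join(cand))
                i += ln
                merged = True
                break
        if not merged:
            out.append(tokens[i])
            i += 1
    return out


@dataclass
class EmbeddingSpace:
    """Dense word vectors over a fixed vocabulary (rows align with tokens)."""

    vocabulary: list[str]
    vectors: np.ndarray  # (n_tokens, dim)

    def __post_init__(self) -> None:
        if len(self.vocabulary) != len(set(self.vocabulary)):
            raise ValueError("vocabulary contains duplicates")
        if self.vectors.shape[0] != len(self.vocabulary):
            raise ValueError("one vector per vocabulary token required")
        self._index = {t: i for i, t in enumerate(self.vocabulary)}
        norms = np.linalg.norm(self.vectors, axis=1)
        norms[norms == 0] = 1.0
        self._unit = self.vectors / norms[:, None]

    def __contains__(self, token: str) -> bool:
        return token in self._index

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def vector(self, token: str) -> np.ndarray:
        return self.vectors[self._index[token]]

    def cosine_similarities(self, token: str) -> np.ndarray:
        """Cosine similarity of `token` to every vocabulary entry."""
        return self._unit @ self._unit[self._index[token]]


def train_embedding(corpus: Iterable[str], window: int = 5, dim: int = 50,
                    min_count: int = 2,
                    phrases: Iterable[str] = ()) -> EmbeddingSpace:
    """Train a deterministic word-embedding space over a plain-text corpus.

    Counts symmetric co-occurrences within ``window`` tokens, weights them
    by positive pointwise mutual information, and factorizes with a dense
    truncated SVD.  Word vectors are ``U_k * sqrt(S_k)``.  The sign of each
    singular vector is fixed by making its largest-magnitude component
    positive, so repeated training on the same corpus is bit-identical.

    Parameters
    ----------
    corpus : iterable of str
        One document per element.
    phrases : iterable of str
        Multi-word keywords to merge into single tokens before counting
        (stored underscore-joined, e.g. ``schlechte_stimmung``).
    """
    phrase_tuples = {tuple(tokenize(p)) for p in phrases if len(tokenize(p)) > 1}
    docs = [_join_phrases(tokenize(doc), phrase_tuples) for doc in corpus]
    docs = [d for d in docs if d]
    if not docs:
        raise ValueError("corpus is empty")

    counts = Counter(t for d in docs for t in d)
    vocab = sorted(t for t, c in counts.items() if c >= min_count)
    n = len(vocab)
    if n < dim:
        raise ValueError(
            f"vocabulary has {n} tokens after min_count={min_count} filtering; "
            f"choose dim <= {n} (got dim={dim})")
    index = {t: i for i, t in enumerate(vocab)}

    co = np.zeros((n, n))
    for d in docs:
        ids = [index.get(t, -1) for t in d]
        for i, ti in enumerate(ids):
            if ti < 0:
                continue
            for j in range(max(0, i - window), min(len(ids), i + window + 1)):
                tj = ids[j]
                if j != i and tj >= 0:
                    co[ti, tj] += 1.0

    total = co.sum()
    if total == 0:
        raise ValueError("no co-occurrences found; corpus documents too short")
    row = co.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log(co * total / (row @ row.T))
    ppmi = np.where(np.isfinite(pmi) & (pmi > 0), pmi, 0.0)

    u, s, _ = np.linalg.svd(ppmi, full_matrices=False)
    u, s = u[:, :dim], s[:dim]
    # deterministic sign: largest-|component| of each singular vector positive
    for k in range(dim):
        if u[np.argmax(np.abs(u[:, k])), k] < 0:
            u[:, k] = -u[:, k]
    vectors = u * np.sqrt(s)
    return EmbeddingSpace(vocabulary=vocab, vectors=vectors)


# --------------------------------------------------------------------------
# lexicon

@dataclass(frozen=True)
class LexiconEntry:
    keyword: str
    provenance: str  # "seed" | "expanded"
    score: float | None = None  # cosine to nearest seed; None for seeds

    def __post_init__(self) -> None:
        if self.provenance not in ("seed", "expanded"):
            raise ValueError(f"bad provenance {self.provenance!r}")


@dataclass
class SymptomLexicon:
    """Per-symptom keyword sets with seed/expanded provenance."""

    entries: dict[str, list[LexiconEntry]]

    def symptoms(self) -> list[str]:
        return [s for s in SYMPTOMS if s in self.entries]

    def keywords(self, symptom: str) -> set[str]:
        return {e.keyword for e in self.entries.get(symptom, [])}

    def seed_keywords(self, symptom: str) -> set[str]:
        return {e.keyword for e in self.entries.get(symptom, []) if e.provenance == "seed"}

    def is_empty(self) -> bool:
        return not any(self.entries.values())

    def to_json(self) -> str:
        payload = {
            s: [
                {"keyword": e.keyword, "provenance": e.provenance, "score": e.score}
                for e in sorted(self.entries[s], key=lambda e: (e.provenance != "seed", e.keyword))
            ]
            for s in self.symptoms()
        }
        return json.dumps(payload, ensure_ascii=False, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SymptomLexicon":
        raw = json.loads(text)
        return cls(entries={
            s: [LexiconEntry(d["keyword"], d["provenance"], d.get("score")) for d in items]
            for s, items in raw.items()
        })

    @classmethod
    def from_seeds(cls, seeds: Sequence[SeedSet]) -> "SymptomLexicon":
        return cls(entries={
            ss.symptom: [LexiconEntry(w, "seed") for w in sorted(ss.words)] for ss in seeds
        })


def expand_lexicon(seeds: Sequence[SeedSet], space: EmbeddingSpace,
                   tau: float = 0.4, k: int = 25,
                   allow: Mapping[str, Iterable[str]] | None = None,
                   deny: Iterable[str] = ()) -> SymptomLexicon:
    """Enrich seed sets with embedding neighbours.

    For every seed word present in the space, up to ``k`` nearest cosine
    neighbours scoring at least ``tau`` are added as ``expanded`` entries;
    ties at equal cosine break lexicographically.  Seeds missing from the
    space contribute no expansions (logged, not an error).  ``allow`` and
    ``deny`` model manual curation: allow-listed words join with score 1.0,
    deny-listed ones never join.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must be in [0,1], got {tau}")
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    deny_norm = {normalize_keyword(w) for w in deny}
    lex: dict[str, list[LexiconEntry]] = {}
    for ss in seeds:
        entries = [LexiconEntry(w, "seed") for w in sorted(ss.words)]
        best: dict[str, float] = {}
        seed_tokens = {_phrase_token(w) for w in ss.words}
        for seed_word in sorted(ss.words):
            tok = _phrase_token(seed_word)
            if tok not in space:
                logger.info("seed %r (%s) absent from embedding space; no expansion",
                            seed_word, ss.symptom)
                continue
            sims = space.cosine_similarities(tok)
            cands = [
                (float(sims[i]), space.vocabulary[i])
                for i in range(len(space.vocabulary))
                if space.vocabulary[i] not in seed_tokens and sims[i] >= tau
            ]
            cands.sort(key=lambda t: (-t[0], t[1]))
            for score, cand_tok in cands[:k]:
                word = cand_tok.replace("_", " ")
                if word in deny_norm or word in ss.words:
                    continue
                if score > best.get(word, -np.inf):
                    best[word] = score
        for word in (allow or {}).get(ss.symptom, []):
            word = normalize_keyword(word)
            if word not in ss.words and word not in deny_norm:
                best.setdefault(word, 1.0)
        entries.extend(LexiconEntry(w, "expanded", round(best[w], 12)) for w in sorted(best))
        lex[ss.symptom] = entries
    return SymptomLexicon(entries=lex)


def match_keywords(text: str, lexicon: SymptomLexicon) -> set[str]:
    """Symptoms whose lexicon has an exact token-sequence match in `text`.

    Matching is token-level after normalization (lowercase, hashtag marker
    stripped): substrings never match, multi-word keywords must appear as a
    contiguous token run.
    """
    tokens = tokenize(text)
    if not tokens:
        return set()
    ngrams: dict[int, set[tuple[str, ...]]] = {}

    def grams(n: int) -> set[tuple[str, ...]]:
        if n not in ngrams:
            ngrams[n] = {tuple(tokens[i:i + n]) for i in range(len(tokens) - n + 1)}
        return ngrams[n]

    matched = set()
    for symptom in lexicon.symptoms():
        for kw in lexicon.keywords(symptom):
            kw_tokens = tuple(kw.split(" "))
            if kw_tokens and len(kw_tokens) <= len(tokens) and kw_tokens in grams(len(kw_tokens)):
                matched.add(symptom)
                break
    return matched
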