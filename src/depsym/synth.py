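"""Synthetic survey cohorts, tweet streams and enrichment corpora.

The real data behind this analysis (a restricted national health survey and
a non-redistributable tweet corpus) cannot ship with the package, so this
module generates stand-ins with the statistical structure the downstream
stages assume:

* weekly symptom-report probabilities following a logistic model with a
  dip/rise structure around the contact-ban weeks (12-18),
* elevated risk for young adult women via sex, age and sex x age log-odds
  offsets,
* log-normal survey weights with mean 1,
* 1-10 tweets per user-week with ~96% single-tweet users, retweets, and
  keyword-bearing texts that are first-person or third-person,
* five symptom categories with strongly unequal base rates (feelings of
  worthlessness rarest, fatigue/energy loss most common).

All generators are deterministic given ``rng_seed``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from depsym.lexicon import SeedSet, SymptomLexicon
from depsym.symptoms import (ITEM_COLUMNS, SURVEY_AGE_GROUPS, SYMPTOMS,
                             TWITTER_AGE_GROUPS, harmonize_age_group)
from depsym.window import StudyWindow


class ConfigError(ValueError):
    """Invalid synthetic configuration; names the offending field."""

    def __init__(self, fieldname: str, message: str):
        self.fieldname = fieldname
        super().__init__(f"{fieldname}: {message}")


#: Symptom base rates: probability of reporting the symptom at all in the
#: reference cell during the pre-ban period.  Ordered from the published
#: survey margins; worthlessness/guilt rarest, fatigue most common.
DEFAULT_BASE_RATES: dict[str, float] = {
    "diminished_interest": 0.38,
    "depressed_mood": 0.27,
    "insomnia_hypersomnia": 0.50,
    "fatigue_energy_loss": 0.54,
    "worthlessness_guilt": 0.14,
}

#: Period log-odds offsets (before, during, after) relative to the pre-ban
#: level: a small rise in low mood during the ban, and a dip in sleep
#: problems, fatigue and worthlessness that partially rebounds afterwards.
DEFAULT_PERIOD_EFFECTS: dict[str, tuple[float, float, float]] = {
    "diminished_interest": (0.0, 0.085, 0.0),
    "depressed_mood": (0.0, 0.05, 0.0),
    "insomnia_hypersomnia": (0.0, -0.12, -0.04),
    "fatigue_energy_loss": (0.0, -0.16, -0.08),
    "worthlessness_guilt": (0.0, -0.086, 0.0),
}


@dataclass(frozen=True)
class DemographicEffects:
    """Log-odds offsets for sex (female vs male), age group (vs youngest)
    and the female x age interaction, on harmonized age labels."""

    sex: float = 0.30
    age: Mapping[str, float] = field(default_factory=lambda: {
        "<18": 0.0, "18-24": 0.20, "25-34": 0.10, "35-49": 0.0, "50+": -0.20,
    })
    sex_age: Mapping[str, float] = field(default_factory=lambda: {
        "<18": 0.0, "18-24": 0.30, "25-34": 0.10, "35-49": 0.0, "50+": 0.0,
    })

    @classmethod
    def null(cls) -> "DemographicEffects":
        zero = {g: 0.0 for g in ("<18", "18-24", "25-34", "35-49", "50+")}
        return cls(sex=0.0, age=zero, sex_age=zero)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic generators.

    Defaults emulate the source study: 9011 survey respondents and ~48.5k
    tweeting users over calendar weeks 1-31 of 2020 with contact-ban bounds
    at weeks 11 and 18, a female-dominant 18-24-modal Twitter sample, and a
    near-even older survey sample.
    """

    n_respondents: int = 9011
    n_users: int = 48549
    weeks: tuple[int, int] = (1, 31)
    period_bounds: tuple[int, int] = (11, 18)
    iso_year: int = 2020
    symptom_base_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_RATES))
    period_effects: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PERIOD_EFFECTS))
    demo_effects: DemographicEffects = field(default_factory=DemographicEffects)
    survey_female_share: float = 0.517
    survey_age_dist: tuple[float, ...] = (0.045, 0.084, 0.137, 0.199, 0.535)
    twitter_female_share: float = 0.839
    twitter_age_dist: tuple[float, ...] = (0.128, 0.577, 0.129, 0.106, 0.060)
    #: P(1..10 tweets in the user's active week); heavy mass on one tweet
    tweets_per_user: tuple[float, ...] = (
        0.96, 0.016, 0.008, 0.005, 0.004, 0.003, 0.002, 0.001, 0.0006, 0.0004)
    self_reference_rate: float = 0.95
    retweet_rate: float = 0.03
    region_share: float = 0.68
    weight_sigma: float = 0.5
    rng_seed: int = 2020

    def validate(self) -> None:
        if self.n_respondents <= 0:
            raise ConfigError("n_respondents", "must be positive")
        if self.n_users <= 0:
            raise ConfigError("n_users", "must be positive")
        lo, hi = self.weeks
        if lo > hi or lo < 1:
            raise ConfigError("weeks", f"invalid inclusive range {self.weeks}")
        b1, b2 = self.period_bounds
        if not lo <= b1 < b2 <= hi:
            raise ConfigError("period_bounds",
                              f"{self.period_bounds} not strictly increasing inside {self.weeks}")
        for sym, p in self.symptom_base_rates.items():
            if not 0.0 < p < 1.0:
                raise ConfigError("symptom_base_rates", f"{sym}: {p} not in (0,1)")
        for sym in self.symptom_base_rates:
            if sym not in SYMPTOMS:
                raise ConfigError("symptom_base_rates", f"unknown symptom {sym!r}")
        if len(self.tweets_per_user) != 10:
            raise ConfigError("tweets_per_user", "support must be exactly 1..10")
        if any(p < 0 for p in self.tweets_per_user) or not np.isclose(
                sum(self.tweets_per_user), 1.0):
            raise ConfigError("tweets_per_user", "probabilities must be >=0 and sum to 1")
        for name, p in (("self_reference_rate", self.self_reference_rate),
                        ("survey_female_share", self.survey_female_share),
                        ("twitter_female_share", self.twitter_female_share)):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(name, f"{p} not in [0,1]")
        if not 0.0 <= self.retweet_rate < 1.0:
            raise ConfigError("retweet_rate", f"{self.retweet_rate} not in [0,1)")
        for name, dist in (("survey_age_dist", self.survey_age_dist),
                           ("twitter_age_dist", self.twitter_age_dist)):
            if len(dist) != 5 or any(p < 0 for p in dist) or not np.isclose(sum(dist), 1.0):
                raise ConfigError(name, "needs 5 non-negative probabilities summing to 1")
        if self.weight_sigma <= 0:
            raise ConfigError("weight_sigma", "must be positive")

    def window(self) -> StudyWindow:
        """Full-ISO-week study window covering the configured week range."""
        lo, hi = self.weeks
        return StudyWindow(
            start=dt.date.fromisocalendar(self.iso_year, lo, 1),
            end=dt.date.fromisocalendar(self.iso_year, hi, 7),
            period_bounds=self.period_bounds,
        )

    def period_index(self, week: int) -> int:
        b1, b2 = self.period_bounds
        return 0 if week <= b1 else (1 if week <= b2 else 2)

    def with_(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


# --------------------------------------------------------------------------
# survey generator

#: conditional severity split for affected respondents (response 1/2/3)
_SEVERITY_SPLIT = (0.55, 0.30, 0.15)


def generate_survey(config: SyntheticConfig) -> pd.DataFrame:
    """Simulate a cross-sectional survey cohort.

    Each respondent gets a uniform calendar week, sex and age group from the
    configured marginals, a log-normal weight with mean 1, and five ordinal
    item responses (0-3) whose probability of being >= 1 follows the
    logistic model with base rate, period effect and demographic offsets.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 1]))
    n = config.n_respondents
    lo, hi = config.weeks

    week = rng.integers(lo, hi + 1, size=n)
    female = rng.random(n) < config.survey_female_share
    age_idx = rng.choice(5, size=n, p=np.asarray(config.survey_age_dist))
    age = np.array(SURVEY_AGE_GROUPS)[age_idx]
    sigma = config.weight_sigma
    weight = rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma, size=n)

    period = np.array([config.period_index(w) for w in week])
    harm = np.array([harmonize_age_group(a) for a in age])
    de = config.demo_effects
    demo_eta = (de.sex * female
                + np.array([de.age[a] for a in harm])
                + np.array([de.sex_age[a] for a in harm]) * female)

    data = {
        "id": [f"r{i:06d}" for i in range(n)],
        "week": week,
        "sex": np.where(female, "female", "male"),
        "age_group": age,
        "weight": weight,
    }
    for sym in SYMPTOMS:
        base = config.symptom_base_rates[sym]
        pe = np.asarray(config.period_effects[sym])[period]
        p = _expit(_logit(base) + pe + demo_eta)
        affected = rng.random(n) < p
        severity = rng.choice([1, 2, 3], size=n, p=_SEVERITY_SPLIT)
        data[ITEM_COLUMNS[sym]] = np.where(affected, severity, 0)
    return pd.DataFrame(data)


# --------------------------------------------------------------------------
# tweet generator

#: minimal first-person carrier sentences; the keyword slot holds exactly
#: one lexicon entry and every sentence contains a first-person marker
FIRST_PERSON_TEMPLATES = (
    "Ich fühle mich heute so {kw}.",
    "Ich habe seit Wochen {kw}.",
    "Ich leide gerade unter {kw}.",
    "Mir macht {kw} wirklich zu schaffen.",
)

#: third-person / impersonal carriers; free of first-person markers
THIRD_PERSON_TEMPLATES = (
    "Er wirkt heute sehr {kw}.",
    "Sie spricht oft über {kw}.",
    "Der Artikel handelt von {kw}.",
    "Viele Menschen erleben {kw} im Alltag.",
)

_REGIONS = ("BE", "BY", "NW", "SN", "HH")


def generate_tweets(config: SyntheticConfig, lexicon: SymptomLexicon) -> pd.DataFrame:
    """Simulate a stream of tweet-like records.

    Users get demographic attributes from the Twitter marginals, one active
    week (uniform) and a 1-10 tweet count for that week.  Each tweet carries
    exactly one lexicon keyword for a symptom drawn proportionally to
    ``base_rate * exp(period_effect)``, rendered in a first-person carrier
    sentence with probability ``self_reference_rate`` and a third-person one
    otherwise.  Retweets are emitted with ``retweet_rate`` and flagged both
    in ``is_retweet`` and by an ``RT @...:`` prefix.

    Ground-truth columns ``_symptom`` and ``_first_person`` are attached for
    validation; the JSONL writer drops underscore-prefixed columns.
    """
    config.validate()
    if lexicon.is_empty():
        raise ValueError("lexicon is empty; cannot generate symptom tweets")
    symptoms = [s for s in SYMPTOMS if lexicon.keywords(s)]
    if not symptoms:
        raise ValueError("lexicon has no keywords for any symptom")
    keyword_bank = {s: sorted(lexicon.keywords(s)) for s in symptoms}

    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 2]))
    window = config.window()
    lo, hi = config.weeks
    n_users = config.n_users

    # per-period symptom intensity: base rates scaled by period effects
    intensity = np.array([[config.symptom_base_rates[s] * np.exp(config.period_effects[s][p])
                           for s in symptoms] for p in range(3)])
    # weekly volume proportional to total intensity, so each symptom's
    # absolute weekly tweet rate follows base_rate * exp(period_effect)
    week_ids = np.arange(lo, hi + 1)
    week_periods = np.array([config.period_index(int(w)) for w in week_ids])
    week_weights = intensity.sum(axis=1)[week_periods]
    week_weights = week_weights / week_weights.sum()
    rates = intensity / intensity.sum(axis=1, keepdims=True)

    user_week = rng.choice(week_ids, size=n_users, p=week_weights)
    user_female = rng.random(n_users) < config.twitter_female_share
    user_age = np.array(TWITTER_AGE_GROUPS)[
        rng.choice(5, size=n_users, p=np.asarray(config.twitter_age_dist))]
    n_tweets = rng.choice(np.arange(1, 11), size=n_users,
                          p=np.asarray(config.tweets_per_user))

    user_idx = np.repeat(np.arange(n_users), n_tweets)
    m = len(user_idx)
    week = user_week[user_idx]
    period = np.array([config.period_index(w) for w in week])
    u = rng.random(m)
    sym_idx = (u[:, None] > np.cumsum(rates, axis=1)[period]).sum(axis=1)

    first_person = rng.random(m) < config.self_reference_rate
    retweet = rng.random(m) < config.retweet_rate
    tpl_idx = rng.integers(0, 4, size=m)
    day_pick = rng.random(m)
    has_region = rng.random(m) < config.region_share
    region_idx = rng.integers(0, len(_REGIONS), size=m)
    kw_pick = rng.random(m)

    texts = []
    timestamps = []
    for i in range(m):
        sym = symptoms[sym_idx[i]]
        bank = keyword_bank[sym]
        kw = bank[int(kw_pick[i] * len(bank))]
        tpl = (FIRST_PERSON_TEMPLATES if first_person[i] else THIRD_PERSON_TEMPLATES)[tpl_idx[i]]
        text = tpl.format(kw=kw)
        if retweet[i]:
            text = f"RT @user{user_idx[i] % 997}: {text}"
        texts.append(text)
        dates = window.week_dates(int(week[i]))
        timestamps.append(dates[int(day_pick[i] * len(dates))].isoformat())

    return pd.DataFrame({
        "text": texts,
        "timestamp": timestamps,
        "user_id": [f"u{j:07d}" for j in user_idx],
        "is_retweet": retweet,
        "sex": np.where(user_female[user_idx], "female", "male"),
        "age_group": user_age[user_idx],
        "region": [(_REGIONS[region_idx[i]] if has_region[i] else None) for i in range(m)],
        "_symptom": [symptoms[j] for j in sym_idx],
        "_first_person": first_person,
    })


# --------------------------------------------------------------------------
# enrichment corpus generator

#: Default corpus-derived companions per symptom (includes the published
#: low-mood expansion examples).  These are the words the embedding-based
#: expansion is expected to recover from the synthetic corpus.
DEFAULT_RELATED_WORDS: dict[str, tuple[str, ...]] = {
    "diminished_interest": ("interesselos", "gleichgültigkeit", "freudlos"),
    "depressed_mood": ("aussichtslos", "ausweglos", "bedrückt", "entmutigt",
                       "schlechte stimmung"),
    "insomnia_hypersomnia": ("einschlafprobleme", "durchschlafprobleme", "schlafstörung"),
    "fatigue_energy_loss": ("kraftlos", "ausgelaugt", "erschöpft"),
    "worthlessness_guilt": ("enttäuschung", "wertlos", "schuldig", "nicht ertragen"),
}

#: Shared context vocabulary per symptom: seed and related words co-occur
#: with these, which is what makes them embedding neighbours.
CONTEXT_WORDS: dict[str, tuple[str, ...]] = {
    "diminished_interest": ("hobbys", "freude", "unternehmungen", "begeisterung",
                            "alltag", "aktivitäten", "langeweile", "desinteresse"),
    "depressed_mood": ("trübsinn", "schwere", "gedanken", "weinen", "leere",
                       "verzweiflung", "kummer", "seelisch"),
    "insomnia_hypersomnia": ("nacht", "wach", "bett", "grübeln", "aufwachen",
                             "mitternacht", "schlummer", "ruhelos"),
    "fatigue_energy_loss": ("energie", "schlapp", "gerädert", "ausgepowert",
                            "erholung", "pause", "kraft", "tagsüber"),
    "worthlessness_guilt": ("schuld", "scham", "selbstzweifel", "vorwürfe",
                            "belastung", "gewissen", "versagt", "minderwertig"),
}

_DISTRACTOR_WORDS = (
    "fußball", "bundesliga", "tor", "spiel", "mannschaft", "trainer",
    "rezept", "kochen", "backen", "zutaten", "wetter", "sonne", "regen",
    "urlaub", "strand", "meer", "politik", "wahl", "partei", "debatte",
    "börse", "aktien", "kurse", "zinsen",
)


def generate_corpus(config: SyntheticConfig,
                    seed_sets: SeedSet | Sequence[SeedSet],
                    related_words: Mapping[str, Iterable[str]] | Iterable[str] | None = None,
                    docs_per_word: int = 30,
                    distractor_docs: int = 150) -> list[str]:
    """Emit a forum-style enrichment corpus, one document per line element.

    For every seed and related word of a symptom, documents place the word
    among symptom-specific context words, so seeds and related words share
    context distributions and become neighbours in the trained embedding
    space.  Distractor documents from an unrelated vocabulary provide
    competition.  Deterministic given ``config.rng_seed``.
    """
    config.validate()
    if isinstance(seed_sets, SeedSet):
        seed_sets = [seed_sets]
    if not seed_sets:
        raise ValueError("no seed sets supplied")
    if related_words is None:
        related: dict[str, list[str]] = {
            ss.symptom: list(DEFAULT_RELATED_WORDS.get(ss.symptom, ())) for ss in seed_sets}
    elif isinstance(related_words, Mapping):
        related = {ss.symptom: list(related_words.get(ss.symptom, ())) for ss in seed_sets}
    else:
        listed = list(related_words)
        related = {ss.symptom: listed for ss in seed_sets}
    if not any(related.values()):
        raise ValueError("no related words supplied for any symptom")

    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 3]))
    docs: list[str] = []
    for ss in sorted(seed_sets, key=lambda s: s.symptom):
        ctx = np.array(CONTEXT_WORDS[ss.symptom])
        vocab = sorted(ss.words) + [w.lower() for w in related[ss.symptom]]
        for word in vocab:
            for _ in range(docs_per_word):
                toks = [word] + list(rng.choice(ctx, size=4, replace=False))
                rng.shuffle(toks)
                docs.append(" ".join(toks))
    distract = np.array(_DISTRACTOR_WORDS)
    for _ in range(distractor_docs):
        docs.append(" ".join(rng.choice(distract, size=5, replace=False)))
    order = rng.permutation(len(docs))
    return [docs[i] for i in order]


# --------------------------------------------------------------------------
# serialization

def write_tweets_jsonl(frame: pd.DataFrame, path) -> None:
    """Write tweet records as JSON Lines, dropping generator metadata
    (underscore-prefixed columns)."""
    import json
    cols = [c for c in frame.columns if not c.startswith("_")]
    with open(path, "w", encoding="utf-8") as fh:
        for rec in frame[cols].to_dict(orient="records"):
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def write_survey_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def write_corpus(docs: Sequence[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(docs) + "\n")
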