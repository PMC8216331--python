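"""Tweet filtering, classification and weekly aggregation.

The classification pipeline follows a fixed order mirroring the collection
workflow: window filter, retweet removal, exact keyword match, and
self-reference detection (first-person pronouns/verbs).  Retained tweets
are aggregated into per-symptom weekly series of mean tweets per day, the
measure comparable to the survey's weekly symptom proportions.  Symptoms
whose overall daily tweet frequency stays below a threshold (default 12 a
day) are excluded from further analysis, and the exclusion is reported.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from depsym.lexicon import SymptomLexicon, match_keywords, tokenize
from depsym.symptoms import SYMPTOMS
from depsym.window import DEFAULT_WINDOW, StudyWindow, label_period

logger = logging.getLogger(__name__)

__all__ = [
    "SelfReferenceRules", "DEFAULT_RULES", "detect_self_reference",
    "classify_tweets", "ClassificationResult", "aggregate_weekly",
    "aggregate_weekly_by_demo", "exclude_rare_symptoms", "ExclusionReport",
    "label_period", "read_tweets_jsonl", "write_weekly_csv",
]

#: default first-person pronoun tokens (nominative/dative/accusative and
#: possessive inflections, singular and plural)
_DEFAULT_PRONOUNS = (
    "ich", "mir", "mich", "mein", "meine", "meiner", "meinem", "meinen", "meins",
    "wir", "uns", "unser", "unsere", "unserer", "unserem", "unseren", "unseres",
)

#: common first-person verb forms; token-level, so "fühlt" never matches.
#: Only forms unambiguous in person are listed (e.g. "war", "kann" and
#: "muss" are identical in first and third person singular and excluded).
_DEFAULT_VERBS = (
    "bin", "habe", "hab", "fühle", "fühl", "leide", "denke", "brauche",
    "schlafe", "wache", "schaffe", "ertrage", "glaube", "merke", "weine",
)


@dataclass(frozen=True)
class SelfReferenceRules:
    """Token lists for the syntactic self-reference test."""

    pronouns: frozenset[str] = frozenset(_DEFAULT_PRONOUNS)
    verbs: frozenset[str] = frozenset(_DEFAULT_VERBS)

    @property
    def markers(self) -> frozenset[str]:
        return self.pronouns | self.verbs


DEFAULT_RULES = SelfReferenceRules()


def detect_self_reference(text: str, rules: SelfReferenceRules = DEFAULT_RULES) -> bool:
    """True iff the text contains a first-person pronoun or verb token.

    Case-insensitive and token-level: "mich" in "michael" does not count.
    """
    return any(t in rules.markers for t in tokenize(text))


def _is_retweet(rec: Mapping) -> bool:
    # explicit flag OR the classic "RT @" prefix, for ingest-dialect robustness
    return bool(rec.get("is_retweet")) or str(rec.get("text", "")).startswith("RT @")


def _parse_date(value) -> dt.date | None:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    try:
        return dt.datetime.fromisoformat(str(value)).date()
    except (ValueError, TypeError):
        return None


@dataclass
class ClassificationResult:
    """Retained tweets plus per-stage retention counts (no silent loss)."""

    tweets: pd.DataFrame
    stage_counts: dict[str, int]

    def __len__(self) -> int:
        return len(self.tweets)


_CLASSIFIED_COLUMNS = ["text", "timestamp", "user_id", "sex", "age_group", "region",
                       "calendar_week", "period", "symptoms", "self_referenced"]


def classify_tweets(records: pd.DataFrame | Iterable[Mapping],
                    lexicon: SymptomLexicon,
                    rules: SelfReferenceRules = DEFAULT_RULES,
                    window: StudyWindow = DEFAULT_WINDOW) -> ClassificationResult:
    """Run the fixed filtering pipeline over raw tweet records.

    Stages (in order): parseable timestamp inside the window -> original
    (non-retweet) -> exact keyword match -> self-referenced.  Malformed
    timestamps reject the record with a logged warning.  Retained rows carry
    the matched symptom set, ISO calendar week and contact-ban period.
    """
    if lexicon.is_empty():
        raise ValueError("cannot classify against an empty lexicon")
    if isinstance(records, pd.DataFrame):
        records = records.to_dict(orient="records")
    else:
        records = list(records)

    counts = {"input": len(records)}
    malformed = 0
    in_window = []
    for rec in records:
        date = _parse_date(rec.get("timestamp"))
        if date is None:
            malformed += 1
            continue
        if window.contains(date):
            in_window.append((rec, date))
    if malformed:
        logger.warning("rejected %d records with malformed timestamps", malformed)
    counts["in_window"] = len(in_window)

    originals = [(r, d) for r, d in in_window if not _is_retweet(r)]
    counts["original"] = len(originals)

    matched = []
    for rec, date in originals:
        syms = match_keywords(str(rec.get("text", "")), lexicon)
        if syms:
            matched.append((rec, date, syms))
    counts["keyword_matched"] = len(matched)

    rows = []
    for rec, date, syms in matched:
        if detect_self_reference(str(rec.get("text", "")), rules):
            week = date.isocalendar()[1]
            rows.append({
                "text": rec.get("text"),
                "timestamp": date.isoformat(),
                "user_id": rec.get("user_id"),
                "sex": rec.get("sex", "unknown"),
                "age_group": rec.get("age_group", "unknown"),
                "region": rec.get("region"),
                "calendar_week": week,
                "period": window.period_of_week(week),
                "symptoms": tuple(s for s in SYMPTOMS if s in syms),
                "self_referenced": True,
            })
    counts["self_referenced"] = len(rows)

    logger.info("tweet pipeline retention: %s", counts)
    frame = pd.DataFrame(rows, columns=_CLASSIFIED_COLUMNS)
    return ClassificationResult(tweets=frame, stage_counts=counts)


def _weekly_frame(counts: Mapping, window: StudyWindow,
                  keys: list[str]) -> pd.DataFrame:
    rows = []
    for sym in keys:
        for week in window.weeks:
            days = window.days_in_week(week)
            c = counts.get((sym, week), 0)
            rows.append({
                "source": "twitter", "symptom": sym, "week": week,
                "period": window.period_of_week(week),
                "value": c / days, "count": c, "days": days,
                "partial_week": window.is_partial(week),
            })
    return pd.DataFrame(rows)


def aggregate_weekly(classified: pd.DataFrame | ClassificationResult,
                     window: StudyWindow = DEFAULT_WINDOW,
                     symptoms: Iterable[str] = SYMPTOMS) -> pd.DataFrame:
    """Per-symptom weekly series of mean tweets per day.

    A tweet matching m symptoms contributes to all m series.  The weekly
    value divides the symptom's tweet count by the number of calendar days
    of that week inside the window; weeks without tweets are present with
    value 0, partial edge weeks are flagged.
    """
    if isinstance(classified, ClassificationResult):
        classified = classified.tweets
    counts: dict[tuple[str, int], int] = {}
    for syms, week in zip(classified["symptoms"], classified["calendar_week"]):
        for s in syms:
            counts[(s, week)] = counts.get((s, week), 0) + 1
    return _weekly_frame(counts, window, [s for s in SYMPTOMS if s in set(symptoms)])


def aggregate_weekly_by_demo(classified: pd.DataFrame | ClassificationResult,
                             window: StudyWindow = DEFAULT_WINDOW,
                             symptoms: Iterable[str] = SYMPTOMS) -> pd.DataFrame:
    """Weekly tweets-per-day by (symptom, week, sex, age_group) cell.

    This is the modelling unit for the Twitter regressions: covariate cells
    within weeks, each with its daily tweet rate.  Only cells observed at
    least once anywhere in the data are materialized (zero-filled across
    weeks), so the design reflects the observed demographic composition.
    """
    if isinstance(classified, ClassificationResult):
        classified = classified.tweets
    wanted = [s for s in SYMPTOMS if s in set(symptoms)]
    cells = sorted({(sex, age) for sex, age in
                    zip(classified["sex"], classified["age_group"])})
    counts: dict[tuple, int] = {}
    for syms, week, sex, age in zip(classified["symptoms"], classified["calendar_week"],
                                    classified["sex"], classified["age_group"]):
        for s in syms:
            key = (s, week, sex, age)
            counts[key] = counts.get(key, 0) + 1
    rows = []
    for sym in wanted:
        for week in window.weeks:
            days = window.days_in_week(week)
            for sex, age in cells:
                c = counts.get((sym, week, sex, age), 0)
                rows.append({
                    "source": "twitter", "symptom": sym, "week": week,
                    "period": window.period_of_week(week),
                    "sex": sex, "age_group": age,
                    "value": c / days, "count": c, "days": days,
                })
    return pd.DataFrame(rows)


@dataclass
class ExclusionReport:
    """Outcome of the daily-frequency exclusion rule."""

    retained: set[str]
    excluded: dict[str, float] = field(default_factory=dict)  # symptom -> mean/day
    threshold: float = 12.0


def exclude_rare_symptoms(weekly: pd.DataFrame, threshold: float = 12.0) -> ExclusionReport:
    """Exclude symptoms averaging strictly fewer than `threshold` tweets/day.

    The mean is total tweets over total window days, so partial edge weeks
    carry their actual day counts.  Exclusions are logged and reported.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    report = ExclusionReport(retained=set(), threshold=threshold)
    for sym, grp in weekly.groupby("symptom"):
        mean_daily = grp["count"].sum() / grp["days"].sum()
        if mean_daily < threshold:
            report.excluded[sym] = float(mean_daily)
            logger.info("excluding %s: %.2f tweets/day < %g", sym, mean_daily, threshold)
        else:
            report.retained.add(sym)
    return report


# --------------------------------------------------------------------------
# IO

def read_tweets_jsonl(path) -> pd.DataFrame:
    """Read tweet records from UTF-8 JSON Lines (text, timestamp, user_id
    required; is_retweet, sex, age_group, region optional)."""
    frame = pd.read_json(path, lines=True, dtype={"user_id": str},
                         convert_dates=False)
    missing = {"text", "timestamp", "user_id"} - set(frame.columns)
    if missing:
        raise ValueError(f"tweet records missing required keys: {sorted(missing)}")
    return frame


def write_weekly_csv(weekly: pd.DataFrame, path) -> None:
    cols = [c for c in ("source", "symptom", "week", "period", "value",
                        "count", "days", "partial_week") if c in weekly.columns]
    weekly[cols].to_csv(path, index=False)
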