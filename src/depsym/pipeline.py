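"""End-to-end orchestration: synth -> lexicon -> tweets/survey -> models ->
correspondence, from a single reproducible configuration."""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from depsym import correspondence as corr
from depsym import models, survey, synth, tweets
from depsym.lexicon import (SeedSet, SymptomLexicon, build_seed_sets,
                            expand_lexicon, tokenize, train_embedding)
from depsym.symptoms import SYMPTOMS
from depsym.window import StudyWindow

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}/{code}] {message}")


@dataclass
class RunConfig:
    """Everything an end-to-end run needs.

    With no input paths the run is fully synthetic (seed mandatory); paths
    for tweets (JSONL), survey (CSV) or an enrichment corpus (plain text,
    one document per line) replace the corresponding generator.
    """

    synth: synth.SyntheticConfig = field(default_factory=synth.SyntheticConfig)
    seed_table: Mapping[str, list[str]] | None = None
    tau: float = 0.4
    k: int = 25
    embed_dim: int = 50
    embed_window: int = 5
    min_count: int = 2
    allow: Mapping[str, list[str]] | None = None
    deny: tuple[str, ...] = ()
    extra_phrases: tuple[str, ...] = ()
    exclusion_threshold: float = 12.0
    lags: tuple[int, int] = (-4, 4)
    twitter_volume_weights: bool = False
    include_interaction: bool = True
    tweets_path: str | None = None
    survey_path: str | None = None
    corpus_path: str | None = None
    lexicon_path: str | None = None
    outdir: str = "runs/latest"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        synth_raw = raw.pop("synth", {})
        demo_raw = synth_raw.pop("demo_effects", None)
        if demo_raw is not None:
            synth_raw["demo_effects"] = synth.DemographicEffects(**demo_raw)
        for key in ("weeks", "period_bounds", "tweets_per_user",
                    "survey_age_dist", "twitter_age_dist"):
            if key in synth_raw:
                synth_raw[key] = tuple(synth_raw[key])
        for key in ("symptom_base_rates", "period_effects"):
            if key in synth_raw:
                synth_raw[key] = {k: (tuple(v) if isinstance(v, list) else v)
                                  for k, v in synth_raw[key].items()}
        cfg_kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name == "synth":
                continue
            if f.name in raw:
                val = raw[f.name]
                if f.name in ("lags", "deny", "extra_phrases") and isinstance(val, list):
                    val = tuple(val)
                cfg_kwargs[f.name] = val
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise StageError("config", "unknown_keys", f"unrecognized config keys {sorted(unknown)}")
        return cls(synth=synth.SyntheticConfig(**synth_raw), **cfg_kwargs)


def _collect_phrases(seeds: list[SeedSet], config: RunConfig) -> list[str]:
    phrases = set(config.extra_phrases)
    for ss in seeds:
        phrases.update(w for w in ss.words if " " in w)
        phrases.update(w for w in synth.DEFAULT_RELATED_WORDS.get(ss.symptom, ())
                       if " " in w)
    for words in (config.allow or {}).values():
        phrases.update(w for w in words if " " in w)
    return sorted(phrases)


def build_default_lexicon(config: RunConfig | None = None,
                          corpus: list[str] | None = None) -> SymptomLexicon:
    """The shipped lexicon: default seeds expanded over the default
    synthetic enrichment corpus (or a supplied one)."""
    config = config or RunConfig()
    seeds = build_seed_sets(config.seed_table)
    if corpus is None:
        corpus = synth.generate_corpus(config.synth, seeds)
    phrases = _collect_phrases(seeds, config)
    counts = Counter(t for doc in corpus for t in tokenize(doc))
    dim = min(config.embed_dim,
              sum(1 for c in counts.values() if c >= config.min_count))
    space = train_embedding(corpus, window=config.embed_window, dim=dim,
                            min_count=config.min_count, phrases=phrases)
    return expand_lexicon(seeds, space, tau=config.tau, k=config.k,
                          allow=config.allow, deny=config.deny)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and write outputs plus a JSON report.

    Identical config and seed produce a byte-identical report.  Any stage
    failure aborts with :class:`StageError` naming the stage.
    """
    try:
        config.synth.validate()
    except synth.ConfigError as exc:
        raise StageError("config", "invalid_synth", str(exc)) from exc
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.synth.rng_seed, "stages": {}}

    # ---- lexicon ----------------------------------------------------------
    try:
        if config.lexicon_path:
            lexicon = SymptomLexicon.from_json(
                Path(config.lexicon_path).read_text(encoding="utf-8"))
        else:
            seeds = build_seed_sets(config.seed_table)
            if config.corpus_path:
                corpus = Path(config.corpus_path).read_text(
                    encoding="utf-8").splitlines()
            else:
                corpus = synth.generate_corpus(config.synth, seeds)
                synth.write_corpus(corpus, outdir / "corpus.txt")
            lexicon = build_default_lexicon(config, corpus)
        (outdir / "lexicon.json").write_text(lexicon.to_json(), encoding="utf-8")
        report["stages"]["lexicon"] = {
            s: {"seeds": len(lexicon.seed_keywords(s)),
                "total": len(lexicon.keywords(s))}
            for s in lexicon.symptoms()}
    except (ValueError, OSError) as exc:
        raise StageError("lexicon", "build_failed", str(exc)) from exc

    # ---- data -------------------------------------------------------------
    window = config.synth.window()
    try:
        if config.tweets_path:
            tweet_records = tweets.read_tweets_jsonl(config.tweets_path)
        else:
            tweet_records = synth.generate_tweets(config.synth, lexicon)
            synth.write_tweets_jsonl(tweet_records, outdir / "tweets.jsonl")
        if config.survey_path:
            survey_records = survey.read_survey_csv(config.survey_path)
        else:
            survey_records = synth.generate_survey(config.synth)
            synth.write_survey_csv(survey_records, outdir / "survey.csv")
    except (ValueError, OSError) as exc:
        raise StageError("synth", "generation_failed", str(exc)) from exc

    # ---- tweets -----------------------------------------------------------
    try:
        classified = tweets.classify_tweets(tweet_records, lexicon, window=window)
        weekly_tw = tweets.aggregate_weekly(classified, window)
        excl = tweets.exclude_rare_symptoms(weekly_tw, config.exclusion_threshold)
        retained = [s for s in SYMPTOMS if s in excl.retained]
        tweets.write_weekly_csv(weekly_tw, outdir / "twitter_weekly.csv")
        report["stages"]["tweets"] = {
            "retention": classified.stage_counts,
            "excluded_symptoms": {s: round(v, 4) for s, v in sorted(excl.excluded.items())},
            "retained_symptoms": retained,
        }
    except ValueError as exc:
        raise StageError("tweets", "classification_failed", str(exc)) from exc

    # ---- survey -----------------------------------------------------------
    try:
        survey_records = survey.attach_binary_outcomes(survey_records)
        weekly_sv = survey.aggregate_weekly_weighted(survey_records, window)
        survey.write_weekly_csv(weekly_sv, outdir / "survey_weekly.csv")
        report["stages"]["survey"] = {
            "n_respondents": int(len(survey_records)),
            "weeks_missing": int(weekly_sv["missing"].sum()),
        }
    except ValueError as exc:
        raise StageError("survey", "aggregation_failed", str(exc)) from exc

    # ---- models -----------------------------------------------------------
    table1, table2, weekly_margins = [], [], []
    convergence: dict[str, bool] = {}
    wald_p: dict[str, float] = {}
    try:
        cells = tweets.aggregate_weekly_by_demo(classified, window, symptoms=retained) \
            if retained else pd.DataFrame()
        for sym in SYMPTOMS:
            jobs = [("survey", survey_records, "weight")]
            if sym in retained:
                jobs.append(("twitter", cells[cells["symptom"] == sym],
                             "count" if config.twitter_volume_weights else None))
            for source, data, wcol in jobs:
                spec3 = models.ModelSpec(
                    source=source, symptom=sym, time_term="period3",
                    include_interaction=config.include_interaction,
                    weight_col=wcol, period_bounds=config.synth.period_bounds,
                    week_range=config.synth.weeks)
                fit3 = models.fit(spec3, data)
                convergence[f"{source}/{sym}"] = fit3.converged
                for m in models.predictive_margins(fit3, at="period"):
                    table1.append({"source": source, "symptom": sym, "period": m.level,
                                   "margin": m.margin, "ci_low": m.ci_low,
                                   "ci_high": m.ci_high})
                wald_p[f"{source}/{sym}"] = models.wald_period_test(fit3).p_value
                for c in models.pairwise_contrasts(fit3):
                    table2.append({"source": source, "symptom": sym,
                                   "contrast": c.description, "p_value": c.p_value})
                spec5 = dataclasses.replace(spec3, time_term="poly4_week")
                fit5 = models.fit(spec5, data)
                convergence[f"{source}/{sym}/poly4"] = fit5.converged
                for m in models.predictive_margins(fit5, at="week"):
                    weekly_margins.append({"source": source, "symptom": sym,
                                           "week": m.level, "margin": m.margin,
                                           "se": m.se})
        pd.DataFrame(table1).to_csv(outdir / "table1.csv", index=False)
        pd.DataFrame(table2).to_csv(outdir / "table2.csv", index=False)
        margins_df = pd.DataFrame(weekly_margins)
        margins_df.to_csv(outdir / "weekly_margins.csv", index=False)
        report["stages"]["models"] = {
            "convergence": convergence,
            "wald_p": {k: round(v, 6) for k, v in wald_p.items()},
        }
    except ValueError as exc:
        raise StageError("models", "fit_failed", str(exc)) from exc

    # ---- correspondence ---------------------------------------------------
    if retained:
        try:
            lo, hi = config.lags
            results = corr.correlate_sources(
                margins_df[margins_df["source"] == "survey"],
                margins_df[margins_df["source"] == "twitter"],
                symptoms=retained, lags=range(lo, hi + 1))
            corr.correspondence_frame(results).to_csv(
                outdir / "correspondence.csv", index=False)
            report["stages"]["correspondence"] = {
                r.symptom: {"rho": round(r.rho, 4), "p": round(r.p_value, 6),
                            "n_weeks": r.n_weeks, "best_lag": r.best_lag}
                for r in results}
        except ValueError as exc:
            raise StageError("correspondence", "correlation_failed", str(exc)) from exc
    else:
        logger.warning("all symptoms excluded; correspondence stage skipped")
        report["stages"]["correspondence"] = {"skipped": "all symptoms excluded"}

    report_text = json.dumps(report, ensure_ascii=False, indent=2, sort_keys=True)
    (outdir / "report.json").write_text(report_text + "\n", encoding="utf-8")
    return report
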