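"""Cross-source agreement between survey and Twitter weekly series.

The headline statistic is the Spearman rank-order correlation, per symptom,
between the two sources' smoothed weekly predictive margins: rank-based
because the sources live on incommensurable scales (weighted proportions vs
tweets/day), so only the monotone co-movement is meaningful.  An
exploratory integer-week lag scan operationalizes the visual impression
that the social-media signal can lead the survey signal: rho is recomputed
with the Twitter series shifted by each lag, and a negative best lag means
Twitter reacts earlier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    defined: bool = True


def spearman(x: Iterable[float], y: Iterable[float]) -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties.

    rho is the Pearson correlation of the rank vectors; the p-value uses the
    t approximation with n-2 degrees of freedom.  A constant input leaves
    rho undefined, returned as a flagged NaN result instead of raising.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values must be dropped pairwise upstream")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant input vector; Spearman rho undefined")
        return SpearmanResult(np.nan, np.nan, len(x), defined=False)
    rho, p = scipy.stats.spearmanr(x, y)
    return SpearmanResult(float(rho), float(p), len(x))


def exact_permutation_p(x: Iterable[float], y: Iterable[float]) -> float:
    """Exact two-sided permutation p-value for Spearman rho (n <= 10)."""
    import itertools
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n = len(x)
    if n > 10:
        raise ValueError("exact permutation p only supported for n <= 10")
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        r = np.corrcoef(rx, np.asarray(perm))[0, 1]
        count += abs(r) >= obs - 1e-12
        total += 1
    return count / total


@dataclass
class CorrespondenceResult:
    """Per-symptom agreement between the two sources' weekly series."""

    symptom: str
    rho: float
    p_value: float
    n_weeks: int
    defined: bool
    best_lag: int | None = None
    lag_profile: dict[int, float] = field(default_factory=dict)


def _series_by_week(frame: pd.DataFrame, symptom: str,
                    value_col: str) -> dict[int, float]:
    sub = frame[frame["symptom"] == symptom]
    return {int(w): float(v) for w, v in zip(sub["week"], sub[value_col])
            if np.isfinite(v)}


def correlate_sources(survey_margins: pd.DataFrame,
                      twitter_margins: pd.DataFrame,
                      symptoms: Iterable[str] | None = None,
                      lags: Iterable[int] = range(-4, 5),
                      value_col: str = "margin") -> list[CorrespondenceResult]:
    """Spearman correspondence per symptom, with an integer-week lag scan.

    Inputs are tidy frames (symptom, week, <value_col>), normally the
    model-smoothed weekly margins of each source.  rho at lag 0 is the
    headline value; for each lag l the Twitter series is shifted so survey
    week w is paired with Twitter week w + l, rho is recomputed on the
    overlap (lags with under 3 overlapping weeks are skipped, logged), and
    best_lag maximizes rho (ties break toward the smallest |lag|).
    """
    if symptoms is None:
        symptoms = [s for s in survey_margins["symptom"].unique()
                    if s in set(twitter_margins["symptom"])]
    lags = sorted(set(int(l) for l in lags))
    if 0 not in lags:
        raise ValueError("lag scan must include lag 0 (the headline value)")
    results = []
    for sym in symptoms:
        sv = _series_by_week(survey_margins, sym, value_col)
        tw = _series_by_week(twitter_margins, sym, value_col)
        profile: dict[int, float] = {}
        head: SpearmanResult | None = None
        for lag in lags:
            weeks = sorted(w for w in sv if (w + lag) in tw)
            if len(weeks) < 3:
                logger.info("%s: lag %+d has %d overlapping weeks, skipped",
                            sym, lag, len(weeks))
                continue
            res = spearman([sv[w] for w in weeks], [tw[w + lag] for w in weeks])
            if lag == 0:
                head = res
            if res.defined:
                profile[lag] = res.rho
        if head is None:
            raise ValueError(f"{sym}: fewer than 3 overlapping weeks at lag 0")
        best = (min(profile, key=lambda l: (-profile[l], abs(l), l))
                if profile else None)
        results.append(CorrespondenceResult(
            symptom=sym, rho=head.rho, p_value=head.p_value, n_weeks=head.n,
            defined=head.defined, best_lag=best, lag_profile=profile))
    return results


def correspondence_frame(results: list[CorrespondenceResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"symptom": r.symptom, "rho": r.rho, "p": r.p_value, "n": r.n_weeks,
         "best_lag": r.best_lag}
        for r in results
    ])
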