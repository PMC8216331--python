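"""Survey-side processing: dichotomization and weighted weekly aggregation.

PHQ-8 item responses arrive on the 0-3 frequency scale ("not at all" to
"nearly every day") and are collapsed to not-at-all-affected (0) versus
affected (>= 1), mirroring the binary presence signal extractable from
tweets.  Weekly series are survey-weighted proportions; weeks without
respondents are flagged missing rather than set to zero.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from depsym.symptoms import ITEM_COLUMNS, SYMPTOMS
from depsym.window import StudyWindow

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("id", "week", "sex", "age_group", "weight") + tuple(ITEM_COLUMNS.values())


def dichotomize(response):
    """Collapse a 0-3 item response to affected (1) vs not affected (0).

    Vectorized; out-of-range or missing responses become NaN (available-case
    handling happens per item downstream, with a logged count).
    """
    arr = pd.to_numeric(pd.Series(np.atleast_1d(response)), errors="coerce")
    valid = arr.isin([0, 1, 2, 3])
    out = np.where(arr > 0, 1.0, 0.0)
    out = np.where(valid, out, np.nan)
    if np.isscalar(response) or np.ndim(response) == 0:
        return float(out[0]) if np.isfinite(out[0]) else np.nan
    return out


def read_survey_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(REQUIRED_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"survey CSV missing columns: {sorted(missing)}")
    if (frame["weight"] <= 0).any():
        raise ValueError("survey weights must be positive")
    return frame


def attach_binary_outcomes(records: pd.DataFrame) -> pd.DataFrame:
    """Add a dichotomized column ``y_<symptom>`` per item, NaN where the raw
    response is missing or out of range (counts logged)."""
    out = records.copy()
    for sym in SYMPTOMS:
        col = ITEM_COLUMNS[sym]
        y = dichotomize(out[col].to_numpy())
        n_missing = int(np.isnan(y).sum())
        if n_missing:
            logger.info("%s: %d responses missing/out of range, excluded per item",
                        sym, n_missing)
        out[f"y_{sym}"] = y
    return out


def aggregate_weekly_weighted(records: pd.DataFrame,
                              window: StudyWindow,
                              symptoms: Iterable[str] = SYMPTOMS) -> pd.DataFrame:
    """Per-symptom weekly weighted proportions of affected respondents.

    value(week) = sum(w_i * y_i) / sum(w_i) over that week's respondents
    with a valid item response; invariant to rescaling all weights.  Weeks
    with no usable respondents get value NaN and ``missing=True`` so
    downstream models can skip them explicitly.
    """
    if (records["weight"] <= 0).any():
        raise ValueError("survey weights must be positive")
    recs = records
    if not any(c.startswith("y_") for c in recs.columns):
        recs = attach_binary_outcomes(recs)
    wanted = [s for s in SYMPTOMS if s in set(symptoms)]
    rows = []
    for sym in wanted:
        ycol = f"y_{sym}"
        for week in window.weeks:
            sub = recs[(recs["week"] == week) & recs[ycol].notna()]
            if len(sub):
                w = sub["weight"].to_numpy()
                value = float(np.average(sub[ycol].to_numpy(), weights=w))
                missing = False
            else:
                value, missing = np.nan, True
                logger.info("survey week %d has no usable responses for %s", week, sym)
            rows.append({
                "source": "survey", "symptom": sym, "week": week,
                "period": window.period_of_week(week),
                "value": value, "n": len(sub), "missing": missing,
            })
    return pd.DataFrame(rows)


def write_weekly_csv(weekly: pd.DataFrame, path) -> None:
    weekly[["source", "symptom", "week", "period", "value", "n", "missing"]].to_csv(
        path, index=False)
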