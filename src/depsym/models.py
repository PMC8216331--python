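"""Regression models for the weekly symptom series.

Six model shapes are covered by one fitting surface: per symptom, the
survey outcome (binary affected/not) is modelled by weighted logistic
regression and the Twitter outcome (tweets/day in week x sex x age cells)
by linear regression, each with age group, sex and their interaction as
controls (time_term="none"), with calendar week as a centered fourth-degree
polynomial (time_term="poly4_week"), or with the three contact-ban periods
as a categorical term (time_term="period3").  Inference uses robust (HC1)
sandwich covariances; period-level and week-level predictive margins are
averaged model predictions over the estimation sample (observed-covariate
averaging) with delta-method standard errors, and the period term is tested
jointly by a Wald test with pairwise margin contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm

from depsym.symptoms import PERIODS
from depsym.window import label_period

logger = logging.getLogger(__name__)

_AGE_ORDER = ["10-17", "15-17", "<18", "18-24", "25-34", "35-49", "50+", "unknown"]
_SEX_REF = "male"

TIME_TERMS = ("none", "poly4_week", "period3")


def polynomial_time_basis(weeks: np.ndarray, degree: int = 4,
                          center: float | None = None) -> tuple[np.ndarray, float]:
    """Centered powers 1..degree of the week variable.

    Centering is for numerical conditioning only; fitted predictions are
    invariant to the choice of center.  Requires at least ``degree + 1``
    distinct weeks when the center is not supplied (otherwise the polynomial
    is unidentifiable).
    """
    weeks = np.asarray(weeks, dtype=float)
    if center is None:
        if len(np.unique(weeks)) < degree + 1:
            raise ValueError(
                f"need at least {degree + 1} distinct weeks for a degree-{degree} "
                f"polynomial, got {len(np.unique(weeks))}")
        center = float(weeks.mean())
    wc = weeks - center
    return np.column_stack([wc ** d for d in range(1, degree + 1)]), center


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: source decides the family, time_term the smoothing."""

    source: str  # "twitter" | "survey"
    symptom: str
    time_term: str = "none"
    include_interaction: bool = True
    weight_col: str | None = None
    cluster_col: str | None = None
    period_bounds: tuple[int, int] = (11, 18)
    week_range: tuple[int, int] = (1, 31)

    def __post_init__(self) -> None:
        if self.source not in ("twitter", "survey"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.time_term not in TIME_TERMS:
            raise ValueError(f"time_term must be one of {TIME_TERMS}")

    @property
    def family(self) -> str:
        return "binomial_logit" if self.source == "survey" else "gaussian_identity"

    @property
    def outcome_col(self) -> str:
        return f"y_{self.symptom}" if self.source == "survey" else "value"


@dataclass
class _DesignInfo:
    sex_levels: tuple[str, ...]
    age_levels: tuple[str, ...]
    include_interaction: bool
    time_term: str
    period_bounds: tuple[int, int]
    week_range: tuple[int, int]
    week_center: float | None
    columns: list[str] = field(default_factory=list)

    def build(self, df: pd.DataFrame, period: str | None = None,
              week: float | None = None) -> pd.DataFrame:
        """Design matrix for `df`; `period`/`week` override the time value
        for every row (used by predictive margins)."""
        n = len(df)
        cols: dict[str, np.ndarray] = {"const": np.ones(n)}
        female = (df["sex"].to_numpy() == "female").astype(float)
        has_sex = "female" in self.sex_levels and len(self.sex_levels) > 1
        if has_sex:
            cols["sex[female]"] = female
        age = df["age_group"].to_numpy()
        for g in self.age_levels[1:]:
            cols[f"age[{g}]"] = (age == g).astype(float)
            if self.include_interaction and has_sex:
                cols[f"sex[female]:age[{g}]"] = female * (age == g)
        if self.time_term == "period3":
            if period is not None:
                per = np.full(n, period)
            else:
                per = np.array([label_period(int(w), self.period_bounds, self.week_range)
                                for w in df["week"]])
            for lev in ("during", "after"):
                cols[f"period[{lev}]"] = (per == lev).astype(float)
        elif self.time_term == "poly4_week":
            w = np.full(n, float(week)) if week is not None else df["week"].to_numpy(float)
            basis, _ = polynomial_time_basis(w, center=self.week_center)
            for d in range(1, 5):
                cols[f"week_c^{d}"] = basis[:, d - 1]
        X = pd.DataFrame(cols, index=df.index)
        if self.columns:
            X = X[self.columns]
        return X


def _order_levels(values: Iterable[str], order: Sequence[str]) -> tuple[str, ...]:
    present = set(values)
    ordered = [v for v in order if v in present]
    ordered += sorted(present - set(ordered))
    return tuple(ordered)


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        _, _, piv = scipy.linalg.qr(arr, pivoting=True, mode="economic")
        aliased = sorted(X.columns[i] for i in piv[rank:])
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")


@dataclass
class FitResult:
    """Fitted coefficients with sandwich covariance and margin machinery."""

    spec: ModelSpec
    params: pd.Series
    cov: pd.DataFrame
    llf: float
    scale: float
    n: int
    converged: bool
    design: _DesignInfo
    data: pd.DataFrame
    weights: np.ndarray

    @property
    def param_names(self) -> list[str]:
        return list(self.params.index)

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        return X.to_numpy(float) @ self.params.to_numpy()

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        eta = self.linear_predictor(X)
        if self.spec.family == "binomial_logit":
            return 1.0 / (1.0 + np.exp(-eta))
        return eta


def fit(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Fit the specified model by weighted ML (logit IRLS) or WLS.

    Rows with a missing outcome are dropped (logged).  The covariance is the
    HC1 sandwich.  Non-convergence or suspiciously extreme coefficients
    (separation) flag the result rather than raising.  A rank-deficient
    design raises, naming the aliased columns.
    """
    ycol = spec.outcome_col
    for col in ("week", "sex", "age_group", ycol):
        if col not in data.columns:
            raise ValueError(f"data lacks required column {col!r}")
    df = data[data[ycol].notna()].copy()
    dropped = len(data) - len(df)
    if dropped:
        logger.info("%s/%s: dropped %d rows with missing outcome",
                    spec.source, spec.symptom, dropped)
    if not len(df):
        raise ValueError("no usable rows after missing-outcome removal")

    info = _DesignInfo(
        sex_levels=_order_levels(df["sex"], (_SEX_REF, "female", "unknown")),
        age_levels=_order_levels(df["age_group"], _AGE_ORDER),
        include_interaction=spec.include_interaction,
        time_term=spec.time_term,
        period_bounds=spec.period_bounds,
        week_range=spec.week_range,
        week_center=None,
    )
    if spec.time_term == "poly4_week":
        _, info.week_center = polynomial_time_basis(df["week"].to_numpy(float))
    X = info.build(df)
    info.columns = list(X.columns)
    _check_rank(X)

    y = df[ycol].to_numpy(float)
    w = df[spec.weight_col].to_numpy(float) if spec.weight_col else np.ones(len(df))
    if (w <= 0).any():
        raise ValueError("weights must be positive")

    if spec.family == "binomial_logit":
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("binomial outcome must be binary 0/1")
        model = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w)
        res = model.fit(cov_type="HC1", maxiter=100, tol=1e-8)
        converged = bool(getattr(res, "converged", True))
        if np.abs(res.params).max() > 15:
            converged = False
            logger.warning("%s/%s: extreme coefficients, possible separation",
                           spec.source, spec.symptom)
        llf, scale = float(res.llf), 1.0
    else:
        model = sm.WLS(y, X, weights=w)
        res = model.fit(cov_type="HC1")
        converged = True
        llf, scale = float(res.llf), float(res.scale)

    return FitResult(
        spec=spec,
        params=pd.Series(np.asarray(res.params), index=X.columns),
        cov=pd.DataFrame(np.asarray(res.cov_params()), index=X.columns, columns=X.columns),
        llf=llf, scale=scale, n=len(df), converged=converged,
        design=info, data=df, weights=w,
    )


# --------------------------------------------------------------------------
# predictive margins

@dataclass(frozen=True)
class MarginEstimate:
    level: str | int | float
    margin: float
    se: float
    ci_low: float
    ci_high: float


def _margin_and_gradient(fit_: FitResult, period: str | None = None,
                         week: float | None = None) -> tuple[float, np.ndarray]:
    X = fit_.design.build(fit_.data, period=period, week=week)
    mu = fit_.predict(X)
    w = fit_.weights / fit_.weights.sum()
    margin = float(w @ mu)
    arr = X.to_numpy(float)
    if fit_.spec.family == "binomial_logit":
        grad = (w * mu * (1.0 - mu)) @ arr
    else:
        grad = w @ arr
    return margin, grad


def _margin_estimate(fit_: FitResult, level, period=None, week=None) -> MarginEstimate:
    m, g = _margin_and_gradient(fit_, period=period, week=week)
    var = float(g @ fit_.cov.to_numpy() @ g)
    se = float(np.sqrt(max(var, 0.0)))
    z = scipy.stats.norm.ppf(0.975)
    lo, hi = m - z * se, m + z * se
    if fit_.spec.family == "binomial_logit":
        lo, hi = max(lo, 0.0), min(hi, 1.0)
    return MarginEstimate(level=level, margin=m, se=se, ci_low=lo, ci_high=hi)


def predictive_margins(fit_: FitResult, at: str = "period",
                       weeks: Iterable[int] | None = None) -> list[MarginEstimate]:
    """Predictive margins at each contact-ban period or at each week.

    The focal time variable is set to the requested level for every row of
    the estimation sample; predictions are averaged with the estimation
    weights and the standard error follows by the delta method.
    """
    if not fit_.converged:
        raise ValueError("cannot compute margins from a non-converged fit")
    if at == "period":
        if fit_.spec.time_term != "period3":
            raise ValueError("period margins need a model with time_term='period3'")
        return [_margin_estimate(fit_, lev, period=lev) for lev in PERIODS]
    if at == "week":
        if fit_.spec.time_term != "poly4_week":
            raise ValueError("week margins need a model with time_term='poly4_week'")
        if weeks is None:
            lo, hi = fit_.spec.week_range
            weeks = range(lo, hi + 1)
        return [_margin_estimate(fit_, wk, week=float(wk)) for wk in weeks]
    raise ValueError("at must be 'period' or 'week'")


def margins_frame(margins: list[MarginEstimate], spec: ModelSpec) -> pd.DataFrame:
    return pd.DataFrame([
        {"source": spec.source, "symptom": spec.symptom, "level": m.level,
         "margin": m.margin, "se": m.se, "ci_low": m.ci_low, "ci_high": m.ci_high}
        for m in margins
    ])


# --------------------------------------------------------------------------
# Wald tests and period contrasts

@dataclass(frozen=True)
class WaldResult:
    statistic: float
    df: tuple[int, int | None]  # (numerator, denominator or None for chi-square)
    p_value: float
    description: str


def _n_clusters(fit_: FitResult) -> int | None:
    col = fit_.spec.cluster_col
    if col is None:
        return None
    return int(fit_.data[col].nunique())


def wald_period_test(fit_: FitResult) -> WaldResult:
    """Joint Wald test that both period coefficients are zero.

    Large-sample chi-square by default; when the spec names a cluster
    variable, an adjusted F with denominator df = n_clusters - 1 is used
    instead (design-based small-sample adjustment).
    """
    names = [c for c in fit_.param_names if c.startswith("period[")]
    if not names:
        raise ValueError("model has no period term")
    b = fit_.params[names].to_numpy()
    V = fit_.cov.loc[names, names].to_numpy()
    stat = float(b @ np.linalg.solve(V, b))
    q = len(names)
    G = _n_clusters(fit_)
    if G is None:
        return WaldResult(stat, (q, None), float(scipy.stats.chi2.sf(stat, q)),
                          "joint chi-square test of period coefficients")
    F = stat / q
    return WaldResult(F, (q, G - 1), float(scipy.stats.f.sf(F, q, G - 1)),
                      f"adjusted Wald F test of period coefficients ({G} clusters)")


def contrast(fit_: FitResult, level_a: str, level_b: str) -> WaldResult:
    """Pairwise contrast of two period margins on the margin scale."""
    for lev in (level_a, level_b):
        if lev not in PERIODS:
            raise ValueError(f"unknown period level {lev!r}")
    if fit_.spec.time_term != "period3":
        raise ValueError("contrasts need a model with time_term='period3'")
    m_a, g_a = _margin_and_gradient(fit_, period=level_a)
    m_b, g_b = _margin_and_gradient(fit_, period=level_b)
    diff = m_a - m_b
    g = g_a - g_b
    var = float(g @ fit_.cov.to_numpy() @ g)
    if var <= 0:
        return WaldResult(0.0, (1, None), 1.0, f"{level_a} vs {level_b}")
    z = diff / np.sqrt(var)
    G = _n_clusters(fit_)
    if G is None:
        p = float(2 * scipy.stats.norm.sf(abs(z)))
        return WaldResult(float(z ** 2), (1, None), p, f"{level_a} vs {level_b}")
    p = float(2 * scipy.stats.t.sf(abs(z), G - 1))
    return WaldResult(float(z ** 2), (1, G - 1), p, f"{level_a} vs {level_b}")


def pairwise_contrasts(fit_: FitResult) -> list[WaldResult]:
    """All three pairwise period contrasts, unadjusted for multiplicity."""
    pairs = [("before", "during"), ("before", "after"), ("during", "after")]
    return [contrast(fit_, a, b) for a, b in pairs]
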