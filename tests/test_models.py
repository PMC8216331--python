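"""Model fitting, margins, polynomial smoothing and Wald machinery."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from depsym import models
from depsym.models import (ModelSpec, contrast, fit, pairwise_contrasts,
                           polynomial_time_basis, predictive_margins,
                           wald_period_test)


def newton_logit(X, y, w=None, tol=1e-12, maxiter=200):
    """Independent brute-force Newton-Raphson weighted-logit oracle."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    w = np.ones(len(y)) if w is None else np.asarray(w, float)
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        mu = 1.0 / (1.0 + np.exp(-X @ beta))
        grad = X.T @ (w * (y - mu))
        hess = X.T @ (X * (w * mu * (1 - mu))[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def well_posed_logit_data(rng, n_per_cell=7, weights=False):
    """Small logit dataset with a guaranteed finite MLE: every sex x age
    cell contains both outcomes, so no separation is possible."""
    rows = []
    for sex in ("male", "female"):
        for age in ("18-24", "50+"):
            n_ones = int(rng.integers(1, n_per_cell))  # 1..n-1 successes
            for j in range(n_per_cell):
                rows.append({
                    "week": int(rng.integers(1, 32)), "sex": sex, "age_group": age,
                    "weight": float(rng.lognormal(0, 0.4)) if weights else 1.0,
                    "y_depressed_mood": float(j < n_ones),
                })
    return pd.DataFrame(rows)


def logit_data(n, rng, weights=False, weeks=(1, 31)):
    """Random survey-shaped dataset with a known logistic signal."""
    df = pd.DataFrame({
        "week": rng.integers(weeks[0], weeks[1] + 1, n),
        "sex": rng.choice(["male", "female"], n),
        "age_group": rng.choice(["18-24", "25-34", "50+"], n),
        "weight": rng.lognormal(0, 0.4, n) if weights else np.ones(n),
    })
    eta = -0.3 + 0.4 * (df["sex"] == "female") + 0.3 * (df["age_group"] == "50+")
    df["y_depressed_mood"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return df


class TestFit:
    def test_interceptonly_logit_matches_closed_form(self):
        rng = np.random.default_rng(0)
        n = 200
        df = pd.DataFrame({
            "week": rng.integers(1, 32, n), "sex": "female",
            "age_group": "18-24", "weight": rng.lognormal(0, 0.3, n),
            "y_depressed_mood": (rng.random(n) < 0.3).astype(float),
        })
        res = fit(ModelSpec("survey", "depressed_mood", weight_col="weight"), df)
        p = np.average(df["y_depressed_mood"], weights=df["weight"])
        assert res.params["const"] == pytest.approx(np.log(p / (1 - p)), abs=1e-6)
        [m] = [models._margin_estimate(res, "all")]
        assert m.margin == pytest.approx(p, abs=1e-8)

    def test_irls_matches_newton_oracle_small_n(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            df = well_posed_logit_data(rng, weights=True)
            res = fit(ModelSpec("survey", "depressed_mood",
                                weight_col="weight"), df)
            assert res.converged
            X = res.design.build(res.data).to_numpy(float)
            beta = newton_logit(X, res.data["y_depressed_mood"], res.weights)
            np.testing.assert_allclose(res.params.to_numpy(), beta, atol=1e-6)

    def test_rank_deficient_design_names_aliased_columns(self):
        # age_group duplicates sex -> the interaction block aliases perfectly
        df = pd.DataFrame({
            "week": [1, 2, 3, 4] * 5,
            "sex": ["male", "female"] * 10,
            "age_group": ["18-24", "25-34"] * 10,
            "y_depressed_mood": [0, 1, 1, 0] * 5,
        })
        with pytest.raises(ValueError, match="aliased"):
            fit(ModelSpec("survey", "depressed_mood"), df)

    def test_separation_flagged_not_silent(self):
        df = pd.DataFrame({
            "week": list(range(1, 21)),
            "sex": ["female"] * 20, "age_group": ["18-24"] * 20,
            "y_depressed_mood": [0.0] * 10 + [1.0] * 10,
        })
        res = fit(ModelSpec("survey", "depressed_mood", time_term="period3"), df)
        assert not res.converged
        with pytest.raises(ValueError, match="non-converged"):
            predictive_margins(res, at="period")

    def test_binary_outcome_enforced(self):
        df = pd.DataFrame({"week": [1, 2], "sex": ["male"] * 2,
                           "age_group": ["18-24"] * 2,
                           "y_depressed_mood": [0.4, 1.0]})
        with pytest.raises(ValueError, match="binary"):
            fit(ModelSpec("survey", "depressed_mood"), df)

    def test_parameter_recovery_two_se(self):
        # known period log-odds offsets recovered within 2 SE (spot check;
        # the replicated version runs in the acceptance suite)
        from depsym import synth
        cfg = synth.SyntheticConfig(n_respondents=5000, rng_seed=42)
        cohort = synth.generate_survey(cfg)
        from depsym.survey import attach_binary_outcomes
        cohort = attach_binary_outcomes(cohort)
        res = fit(ModelSpec("survey", "fatigue_energy_loss",
                            time_term="period3", weight_col="weight"), cohort)
        truth = dict(zip(("during", "after"),
                         cfg.period_effects["fatigue_energy_loss"][1:]))
        for lev, tru in truth.items():
            est = res.params[f"period[{lev}]"]
            se = np.sqrt(res.cov.loc[f"period[{lev}]", f"period[{lev}]"])
            assert abs(est - tru) < 2 * se


class TestPolynomialTime:
    def test_fewer_than_five_weeks_errors(self):
        with pytest.raises(ValueError, match="distinct weeks"):
            polynomial_time_basis(np.array([1, 2, 3, 4, 1, 2]))

    def test_predictions_invariant_to_centering(self):
        rng = np.random.default_rng(2)
        weeks = rng.integers(1, 32, 60).astype(float)
        y = 0.1 * weeks + rng.normal(0, 0.5, 60)
        preds = []
        for center in (None, 0.0):
            basis, _ = polynomial_time_basis(
                weeks, center=weeks.mean() if center is None else center)
            X = np.column_stack([np.ones(60), basis])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            preds.append(X @ beta)
        np.testing.assert_allclose(preds[0], preds[1], atol=1e-8)

    def test_gaussian_five_weeks_interpolates_cell_means(self):
        # degree-4 polynomial through 5 distinct weeks is saturated in time:
        # weekly margins must reproduce the weekly means exactly
        rng = np.random.default_rng(3)
        rows = []
        for week in (3, 9, 14, 20, 28):
            for _ in range(6):
                rows.append({"week": week, "sex": "female", "age_group": "18-24",
                             "value": rng.normal(10 + week, 1)})
        df = pd.DataFrame(rows)
        res = fit(ModelSpec("twitter", "fatigue_energy_loss",
                            time_term="poly4_week"), df)
        margins = {m.level: m.margin for m in
                   predictive_margins(res, at="week", weeks=[3, 9, 14, 20, 28])}
        weekly_means = df.groupby("week")["value"].mean()
        for week, mean in weekly_means.items():
            assert margins[week] == pytest.approx(mean, abs=1e-6)

    def test_degree4_nests_linear_signal(self):
        # with a linear-in-week gaussian signal the quartic fit reproduces
        # the weekly margins of the straight line
        rng = np.random.default_rng(4)
        df = pd.DataFrame({
            "week": np.tile(np.arange(1, 32), 8).astype(float),
            "sex": "female", "age_group": "18-24"})
        df["value"] = 2.0 + 0.5 * df["week"] + rng.normal(0, 0.05, len(df))
        res = fit(ModelSpec("twitter", "fatigue_energy_loss",
                            time_term="poly4_week"), df)
        for m in predictive_margins(res, at="week", weeks=[1, 10, 20, 31]):
            assert m.margin == pytest.approx(2.0 + 0.5 * m.level, abs=0.05)


@pytest.fixture(scope="module")
def weighted_period_fit():
    rng = np.random.default_rng(5)
    df = logit_data(800, rng, weights=True)
    return fit(ModelSpec("survey", "depressed_mood", time_term="period3",
                         weight_col="weight"), df)


@pytest.fixture(scope="module")
def plain_period_fit():
    rng = np.random.default_rng(7)
    df = logit_data(900, rng)
    return fit(ModelSpec("survey", "depressed_mood", time_term="period3"), df)


class TestMargins:
    def test_margins_in_unit_interval_with_ci(self, weighted_period_fit):
        for m in predictive_margins(weighted_period_fit, at="period"):
            assert 0.0 <= m.ci_low <= m.margin <= m.ci_high <= 1.0

    def test_saturated_gaussian_margins_reproduce_cell_means(self):
        df = pd.DataFrame({
            "week": [5, 5, 15, 15, 25, 25],
            "sex": ["male"] * 6, "age_group": ["18-24"] * 6,
            "value": [10.0, 14.0, 7.0, 9.0, 20.0, 24.0],
        })
        res = fit(ModelSpec("twitter", "fatigue_energy_loss",
                            time_term="period3"), df)
        margins = {m.level: m.margin for m in predictive_margins(res, at="period")}
        assert margins == {"before": pytest.approx(12.0),
                           "during": pytest.approx(8.0),
                           "after": pytest.approx(22.0)}

    def test_delta_se_agrees_with_bootstrap(self):
        rng = np.random.default_rng(6)
        df = logit_data(600, rng, weeks=(1, 31))
        spec = ModelSpec("survey", "depressed_mood", time_term="period3")
        base = {m.level: m for m in
                predictive_margins(fit(spec, df), at="period")}
        boots = {lev: [] for lev in base}
        for _ in range(200):
            sample = df.sample(n=len(df), replace=True, random_state=rng.integers(2**31))
            for m in predictive_margins(fit(spec, sample), at="period"):
                boots[m.level].append(m.margin)
        for lev, m in base.items():
            boot_se = np.std(boots[lev], ddof=1)
            assert abs(m.se - boot_se) / boot_se < 0.15


class TestWald:
    def test_statistic_equals_quadratic_form_oracle(self, plain_period_fit):
        res = wald_period_test(plain_period_fit)
        names = ["period[during]", "period[after]"]
        b = plain_period_fit.params[names].to_numpy()
        V = plain_period_fit.cov.loc[names, names].to_numpy()
        oracle = float(b @ np.linalg.inv(V) @ b)
        assert res.statistic == pytest.approx(oracle, rel=1e-10)
        assert res.p_value == pytest.approx(scipy.stats.chi2.sf(oracle, 2))

    def test_self_contrast_zero(self, plain_period_fit):
        res = contrast(plain_period_fit, "during", "during")
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_three_pairwise_contrasts(self, plain_period_fit):
        results = pairwise_contrasts(plain_period_fit)
        assert [r.description for r in results] == [
            "before vs during", "before vs after", "during vs after"]
        assert all(0 <= r.p_value <= 1 for r in results)

    def test_missing_period_term_errors(self):
        rng = np.random.default_rng(8)
        res = fit(ModelSpec("survey", "depressed_mood"), logit_data(100, rng))
        with pytest.raises(ValueError, match="period"):
            wald_period_test(res)

    def test_cluster_adjustment_uses_f_distribution(self):
        rng = np.random.default_rng(9)
        df = logit_data(400, rng)
        df["psu"] = rng.integers(0, 30, len(df))
        res = fit(ModelSpec("survey", "depressed_mood", time_term="period3",
                            cluster_col="psu"), df)
        wald = wald_period_test(res)
        assert wald.df == (2, 29)
        assert wald.p_value == pytest.approx(
            scipy.stats.f.sf(wald.statistic, 2, 29))
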