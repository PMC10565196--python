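"""From-scratch GLM: IRLS against closed forms, oracles and statsmodels."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from phylospatial import GeoTable, fit_glm, likelihood_ratio_test
from phylospatial.geo import ValidationError
from phylospatial.glm import SeparationError, parse_formula


def table_from(cols, outcome="outcome", covariates=("env",)):
    n = len(next(iter(cols.values())))
    df = pd.DataFrame({"id": [f"i{i}" for i in range(n)],
                       "lon": np.linspace(-20, 20, n), "lat": np.linspace(-10, 10, n), **cols})
    return GeoTable(df, outcome_col=outcome, covariate_cols=list(covariates))


def test_balanced_null_slope_zero():
    t = table_from({"outcome": [0.0, 1.0, 0.0, 1.0], "env": [0.0, 0.0, 1.0, 1.0]})
    fit = fit_glm(t, "outcome ~ env")
    assert fit.beta[1] == pytest.approx(0.0, abs=1e-8)
    assert fit.odds_ratios()["env"][0] == pytest.approx(1.0, abs=1e-8)


def test_two_by_two_log_odds_ratio():
    """Saturated 2x2 logistic slope equals the contingency-table log OR.

    Exposed: 10 of 15 positive; unexposed: 4 of 24 positive ->
    OR = (10*20)/(5*4) = 10, slope ln(10).
    """
    y = [1.0] * 10 + [0.0] * 5 + [1.0] * 4 + [0.0] * 20
    x = [1.0] * 15 + [0.0] * 24
    fit = fit_glm(table_from({"outcome": y, "env": x}), "outcome ~ env")
    assert fit.beta[1] == pytest.approx(np.log(10.0), abs=1e-7)
    assert fit.beta[1] == pytest.approx(2.302585, abs=1e-6)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_irls_matches_numeric_likelihood_maximizer(seed):
    rng = np.random.default_rng(seed)
    n = 50
    env = rng.normal(size=n)
    x2 = rng.normal(size=n)
    eta = 0.3 + 0.8 * env - 0.5 * x2
    y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
    t = table_from({"outcome": y, "env": env, "x2": x2}, covariates=("env", "x2"))
    fit = fit_glm(t, "outcome ~ env + x2")

    X = np.column_stack([np.ones(n), env, x2])

    def nll(b):
        e = X @ b
        return -(y @ e - np.logaddexp(0.0, e).sum())

    res = minimize(nll, np.zeros(3), method="BFGS", options={"gtol": 1e-10})
    assert np.max(np.abs(fit.beta - res.x)) < 1e-6


def test_matches_statsmodels(make_table):
    sm = pytest.importorskip("statsmodels.api")
    t = make_table(n=80, seed=7, binary_outcome=True)
    fit = fit_glm(t, "outcome ~ env")
    X = sm.add_constant(t.covariate("env"))
    ref = sm.GLM(t.outcome, X, family=sm.families.Binomial()).fit()
    assert np.max(np.abs(fit.beta - ref.params)) < 1e-8
    assert np.max(np.abs(fit.se - ref.bse)) < 1e-6
    assert fit.loglik == pytest.approx(ref.llf, abs=1e-8)
    assert fit.aic == pytest.approx(ref.aic, abs=1e-6)
    assert np.max(np.abs(fit.pearson_resid - ref.resid_pearson)) < 1e-6


def test_gaussian_equals_ols():
    rng = np.random.default_rng(5)
    n = 40
    env = rng.normal(size=n)
    y = 1.0 + 0.5 * env + rng.normal(size=n)
    fit = fit_glm(table_from({"outcome": y, "env": env}), "outcome ~ env", family="gaussian")
    X = np.column_stack([np.ones(n), env])
    beta_ols = np.linalg.solve(X.T @ X, X.T @ y)
    assert np.allclose(fit.beta, beta_ols, atol=1e-12)
    resid = y - X @ beta_ols
    assert fit.scale == pytest.approx(float(resid @ resid) / n)


def test_fit_invariants(make_table):
    t = make_table(n=60, seed=3, binary_outcome=True)
    fit = fit_glm(t, "outcome ~ env")
    # intercept score equation: fitted probabilities average the outcome mean
    assert fit.fitted.mean() == pytest.approx(t.outcome.mean(), abs=1e-9)
    # OR identities at 1e-9
    ors = fit.odds_ratios()["env"]
    i = fit.coef_index("env")
    assert ors[0] == pytest.approx(np.exp(fit.beta[i]), abs=1e-9)
    assert ors[1] == pytest.approx(np.exp(fit.beta[i] - 1.959964 * fit.se[i]), abs=1e-9)
    assert ors[2] == pytest.approx(np.exp(fit.beta[i] + 1.959964 * fit.se[i]), abs=1e-9)
    assert fit.aic == 2 * fit.k_params - 2 * fit.loglik
    assert fit.df_resid == fit.n - fit.k_coef


def test_separation_and_rank_errors():
    x = np.linspace(-2, 2, 30)
    y = (x > 0).astype(float)
    with pytest.raises(SeparationError, match="env"):
        fit_glm(table_from({"outcome": y, "env": x}), "outcome ~ env")

    t = table_from({"outcome": (np.arange(30) % 2).astype(float), "env": x, "env2": 2 * x},
                   covariates=("env", "env2"))
    with pytest.raises(ValidationError, match="rank deficient"):
        fit_glm(t, "outcome ~ env + env2")


def test_single_class_outcome_rejected():
    t = table_from({"outcome": np.zeros(10), "env": np.arange(10.0)})
    with pytest.raises(ValidationError, match="single class"):
        fit_glm(t, "outcome ~ env")


def test_formula_parsing():
    assert parse_formula("y ~ a + b") == ("y", ["a", "b"])
    assert parse_formula("y ~ 1") == ("y", [])
    with pytest.raises(ValidationError):
        parse_formula("no tilde")
    t = table_from({"outcome": [0.0, 1.0, 0.0, 1.0], "env": [0.0, 0.0, 1.0, 1.0]})
    with pytest.raises(ValidationError, match="'missing'"):
        fit_glm(t, "outcome ~ missing")


def test_lrt_identities(make_table):
    t = make_table(n=100, seed=11, binary_outcome=True)
    full = fit_glm(t, "outcome ~ env")
    reduced = fit_glm(t, "outcome ~ 1")
    stat, df, p = likelihood_ratio_test(full, reduced)
    assert df == 1 and stat >= 0
    # statistic equals the difference of independently computed deviances
    dev_full = -2.0 * full.loglik
    dev_reduced = -2.0 * reduced.loglik
    assert stat == pytest.approx(dev_reduced - dev_full, abs=1e-9)

    same = likelihood_ratio_test(full, full)
    assert same == (0.0, 0, 1.0)

    with pytest.raises(ValidationError, match="not nested"):
        t2 = GeoTable(t.data.assign(other=np.arange(t.n, dtype=float)),
                      outcome_col="outcome", covariate_cols=["other"])
        likelihood_ratio_test(full, fit_glm(t2, "outcome ~ other"))


def test_lrt_null_calibration():
    """Under a null extra covariate the LRT p-value is uniform."""
    rng = np.random.default_rng(21)
    n, reps = 80, 300
    rejections = 0
    for _ in range(reps):
        env = rng.normal(size=n)
        y = rng.binomial(1, 0.5, size=n).astype(float)
        t = table_from({"outcome": y, "env": env})
        _, _, p = likelihood_ratio_test(fit_glm(t, "outcome ~ env"), fit_glm(t, "outcome ~ 1"))
        rejections += p < 0.05
    from scipy.stats import binom

    lo, hi = binom.interval(0.95, reps, 0.05)
    assert lo <= rejections <= hi


def test_standardize_flag(make_table):
    t = make_table(n=50, seed=13, binary_outcome=True)
    t.data["env"] = t.data["env"] * 7.0 + 3.0
    raw = fit_glm(t, "outcome ~ env")
    std = fit_glm(t, "outcome ~ env", standardize=True)
    sd = t.covariate("env").std(ddof=0)
    assert std.beta[1] == pytest.approx(raw.beta[1] * sd, rel=1e-6)
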