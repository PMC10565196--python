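"""Generalized linear models by iteratively reweighted least squares.

Implements the "naive" regression of the workflow: logistic (binomial,
logit link) and Gaussian (identity link) models with Wald inference, odds
ratios, AIC and Pearson/deviance residuals.  The fit is intentionally
self-contained — dense IRLS with explicit convergence and separation
diagnostics — so that the spatially structured model can reduce to it
exactly when all variance components vanish.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from .geo import GeoTable, ValidationError

__all__ = ["ModelFit", "fit_glm", "likelihood_ratio_test", "parse_formula", "design_matrix"]

Family = Literal["binomial", "gaussian"]

#: Normal quantile for 95% Wald intervals.
Z_95 = 1.959964


class SeparationError(RuntimeError):
    """Perfect (or quasi-)separation in a logistic fit."""


class ConvergenceError(RuntimeError):
    pass


def parse_formula(formula: str) -> tuple[str, list[str]]:
    """Parse 'outcome ~ cov1 + cov2' (use '1' for an intercept-only model)."""
    try:
        lhs, rhs = formula.split("~")
    except ValueError as exc:
        raise ValidationError(f"formula must be 'outcome ~ covariates': {formula!r}") from exc
    outcome = lhs.strip()
    terms = [t.strip() for t in rhs.split("+") if t.strip() and t.strip() != "1"]
    if not outcome:
        raise ValidationError("formula lacks an outcome")
    return outcome, terms


def design_matrix(
    table: GeoTable, covariates: list[str], standardize: bool = False
) -> tuple[np.ndarray, list[str]]:
    """Intercept-first design matrix from named covariate columns."""
    cols = [np.ones(table.n)]
    names = ["(Intercept)"]
    for c in covariates:
        if c not in table.data.columns:
            raise ValidationError(f"missing covariate column '{c}'")
        v = table.covariate(c)
        if np.any(~np.isfinite(v)):
            raise ValidationError(f"non-finite values in covariate '{c}'")
        if standardize:
            sd = v.std(ddof=0)
            if sd == 0:
                raise ValidationError(f"cannot standardize constant covariate '{c}'")
            v = (v - v.mean()) / sd
        cols.append(v)
        names.append(c)
    return np.column_stack(cols), names


@dataclass
class ModelFit:
    """Maximum-likelihood GLM fit with Wald inference.

    Invariants: OR = exp(beta) and its CI bounds are exp(beta +- 1.96 SE);
    AIC = 2k - 2 loglik with k the number of estimated parameters
    (coefficients, plus the scale for the Gaussian family); df_resid =
    n - #coefficients.
    """

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    family: str
    loglik: float
    n: int
    fitted: np.ndarray
    pearson_resid: np.ndarray
    deviance_resid: np.ndarray
    n_iter: int
    grad_norm: float
    converged: bool
    ids: list[str] | None = None
    scale: float | None = None  # Gaussian ML error variance

    # derived (filled in __post_init__)
    z: np.ndarray = field(init=False)
    p: np.ndarray = field(init=False)
    ci_low: np.ndarray = field(init=False)
    ci_high: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.z = self.beta / self.se
        self.p = 2.0 * stats.norm.sf(np.abs(self.z))
        self.ci_low = self.beta - Z_95 * self.se
        self.ci_high = self.beta + Z_95 * self.se

    @property
    def k_coef(self) -> int:
        return len(self.beta)

    @property
    def k_params(self) -> int:
        return self.k_coef + (1 if self.family == "gaussian" else 0)

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.loglik

    @property
    def df_resid(self) -> int:
        return self.n - self.k_coef

    def odds_ratios(self) -> dict[str, tuple[float, float, float]]:
        """name -> (OR, lower, upper); logistic fits only."""
        if self.family != "binomial":
            raise ValidationError("odds ratios are defined for the binomial family only")
        return {
            nm: (float(np.exp(b)), float(np.exp(lo)), float(np.exp(hi)))
            for nm, b, lo, hi in zip(self.names, self.beta, self.ci_low, self.ci_high)
        }

    def coef_index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError as exc:
            raise ValidationError(f"no coefficient named '{name}'") from exc

    def to_dict(self) -> dict:
        out = {
            "family": self.family,
            "n": self.n,
            "loglik": self.loglik,
            "aic": self.aic,
            "df_resid": self.df_resid,
            "converged": self.converged,
            "iterations": self.n_iter,
            "grad_norm": self.grad_norm,
            "coefficients": {
                nm: {
                    "beta": float(b),
                    "se": float(s),
                    "z": float(z),
                    "p": float(p),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                }
                for nm, b, s, z, p, lo, hi in zip(
                    self.names, self.beta, self.se, self.z, self.p, self.ci_low, self.ci_high
                )
            },
        }
        if self.family == "binomial":
            out["odds_ratios"] = {
                nm: {"or": o, "ci_low": lo, "ci_high": hi}
                for nm, (o, lo, hi) in self.odds_ratios().items()
            }
        return out


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log(1 + e^eta) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_glm(
    table: GeoTable,
    formula: str,
    family: Family = "binomial",
    standardize: bool = False,
    max_iter: int = 100,
    tol_score: float = 1e-8,
    tol_dev: float = 1e-10,
) -> ModelFit:
    """Fit a GLM by IRLS (logistic) or closed-form least squares (Gaussian).

    Convergence: max |score| < ``tol_score`` or relative deviance change <
    ``tol_dev``.  Quasi-separation (any |beta| > 15 while the deviance is
    still falling) raises :class:`SeparationError` naming the covariate;
    rank deficiency and non-convergence raise with diagnostics.
    """
    outcome, covariates = parse_formula(formula)
    if table.outcome_col is None:
        table = GeoTable(
            table.data,
            id_col=table.id_col,
            lon_col=table.lon_col,
            lat_col=table.lat_col,
            outcome_col=outcome,
            covariate_cols=covariates,
        )
    elif table.outcome_col != outcome:
        raise ValidationError(
            f"formula outcome '{outcome}' != table outcome '{table.outcome_col}'"
        )
    X, names = design_matrix(table, covariates, standardize=standardize)
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise ValidationError("design matrix is rank deficient")

    if family == "gaussian":
        y = table.outcome
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        scale = float(resid @ resid) / n  # ML variance
        loglik = -0.5 * n * (np.log(2 * np.pi * scale) + 1.0)
        xtx_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(xtx_inv) * (resid @ resid) / (n - k))
        sd = np.sqrt(scale)
        return ModelFit(
            names=names,
            beta=beta,
            se=se,
            family="gaussian",
            loglik=loglik,
            n=n,
            fitted=X @ beta,
            pearson_resid=resid / sd,
            deviance_resid=resid / sd,
            n_iter=1,
            grad_norm=0.0,
            converged=True,
            ids=table.ids,
            scale=scale,
        )

    if family != "binomial":
        raise ValidationError(f"unsupported family '{family}'")
    y = table.require_binary_outcome()

    beta = np.zeros(k)
    deviance = np.inf
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        new_dev = -2.0 * _bernoulli_loglik(y, eta)
        grad_norm = float(np.max(np.abs(score)))
        dev_drop = deviance - new_dev
        if grad_norm < tol_score or (np.isfinite(deviance) and abs(dev_drop) < tol_dev * (abs(new_dev) + 1)):
            deviance = new_dev
            break
        if np.max(np.abs(beta)) > 15.0 and dev_drop > 0:
            worst = names[int(np.argmax(np.abs(beta)))]
            raise SeparationError(
                f"perfect or quasi-separation detected (|beta| > 15 for '{worst}')"
            )
        deviance = new_dev
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix at iteration {it}") from exc
        beta = beta + step
    else:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations (grad_norm={grad_norm:.3g})"
        )

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    se = np.sqrt(np.diag(cov))
    loglik = _bernoulli_loglik(y, eta)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev_i = -2.0 * (y * np.log(np.where(y == 1, mu, 1)) + (1 - y) * np.log(np.where(y == 0, 1 - mu, 1)))
    return ModelFit(
        names=names,
        beta=beta,
        se=se,
        family="binomial",
        loglik=loglik,
        n=n,
        fitted=mu,
        pearson_resid=(y - mu) / np.sqrt(w),
        deviance_resid=np.sign(y - mu) * np.sqrt(np.clip(dev_i, 0.0, None)),
        n_iter=it,
        grad_norm=float(np.max(np.abs(X.T @ (y - mu)))),
        converged=True,
        ids=table.ids,
    )


def likelihood_ratio_test(full: ModelFit, reduced: ModelFit) -> tuple[float, int, float]:
    """LRT of nested GLMs: 2(l_full - l_reduced) ~ chi2 on the df difference."""
    if full.n != reduced.n:
        raise ValidationError("models were fitted to different numbers of rows")
    if not set(reduced.names) <= set(full.names):
        raise ValidationError("models are not nested (reduced terms not a subset of full)")
    df = full.k_coef - reduced.k_coef
    if df < 0:
        raise ValidationError("'full' model has fewer coefficients than 'reduced'")
    stat = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return float(stat), df, p
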